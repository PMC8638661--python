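"""Simulation of biparental selfing populations.

Emulates the structure of a narrow-base cross between two inbred parents:
an F2 mapping population in which every plant founds a *lineage*, F3
families and F4 bulks produced by selfing, and a recombinant-inbred-line
(RIL) population carried to F7 by single-seed descent (SSD).  Marker
panels mix dominant (presence/absence, DArT-like) and codominant
(microsatellite/GBS-like) assays, and additive polygenic traits with a
configurable narrow-sense heritability — optionally including a major
dwarfing gene — are scored in one or more environments.

Meiosis uses Haldane's map function (no crossover interference):
recombination between adjacent loci at distance ``d`` cM occurs with
probability ``r = (1 - exp(-2 d / 100)) / 2``; chromosomes assort
independently.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Individual",
    "Population",
    "TraitModel",
    "make_cross",
    "meiosis",
    "advance",
    "make_ril_population",
    "ascertain_markers",
    "generation_panels",
    "sample_trait_model",
    "breeding_values",
    "simulate_trait",
    "mask_genotypes",
    "simulate_dataset",
    "simulate_type_separated",
    "SimulatedDataset",
]

GENERATIONS = ("P1", "P2", "F1", "F2", "F3", "F4", "F5", "F6", "F7")
_GEN_INDEX = {g: i for i, g in enumerate(GENERATIONS)}


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated biparental population.

    Defaults mirror the study conditions the package targets: a hexaploid
    oat-like genome of 21 chromosomes, ~420 mapped loci (close to a
    401-marker common panel), three-quarters of loci assayed as dominant
    markers, 194 F2 plants and 227 F7 RILs.
    """

    n_chromosomes: int = 21
    chrom_length: float = 100.0  # cM
    n_markers: int = 20  # loci per chromosome
    prop_dominant: float = 0.75
    n_f2: int = 194
    n_ril: int = 227
    sibs_per_family: int = 8  # F3 family / F4 bulk size
    n_qtl: int = 40
    qtl_effect_scale: float = 1.0  # trait units per allele substitution
    major_gene: tuple | None = None  # (chromosome label or index, cM, effect)
    h2: float = 0.5  # narrow-sense heritability at the analysis unit
    n_environments: int = 2
    env_var_fraction: float = 0.3  # share of non-genetic variance in env main effect
    missing_rate: float = 0.0
    common_marker_overlap: float = 1.0  # fraction of loci shared by F2 and RIL panels
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "n_markers": self.n_markers,
            "n_f2": self.n_f2,
            "n_ril": self.n_ril,
            "sibs_per_family": self.sibs_per_family,
            "n_environments": self.n_environments,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.n_qtl < 0:
            raise ValueError(f"n_qtl must be non-negative, got {self.n_qtl!r}")
        if self.chrom_length <= 0:
            raise ValueError(f"chrom_length must be positive, got {self.chrom_length!r}")
        if self.qtl_effect_scale < 0:
            raise ValueError(
                f"qtl_effect_scale must be non-negative, got {self.qtl_effect_scale!r}"
            )
        fractions = {
            "prop_dominant": self.prop_dominant,
            "h2": self.h2,
            "env_var_fraction": self.env_var_fraction,
            "common_marker_overlap": self.common_marker_overlap,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate!r}")
        if self.major_gene is not None:
            if len(self.major_gene) != 3:
                raise ValueError(
                    "major_gene must be (chromosome, position_cm, effect), "
                    f"got {self.major_gene!r}"
                )
            _, pos, _ = self.major_gene
            if not 0.0 <= float(pos) <= self.chrom_length:
                raise ValueError(
                    f"major_gene position {pos!r} outside chromosome length "
                    f"{self.chrom_length!r}"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """Named child RNG streams spawned from one root seed.

    Each stage (genome layout, meiosis, marker ascertainment, trait,
    masking) draws from its own stream, so stages are independently
    reproducible.
    """
    names = ("genome", "meiosis", "markers", "trait", "masking")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# core containers


@dataclasses.dataclass
class Individual:
    id: str
    generation: str
    lineage: str | None  # F2-ancestor id; None for P1/P2/F1
    haplotypes: np.ndarray  # (2, n_loci) uint8, allele 0 = parent-1 "A", 1 = "B"


@dataclasses.dataclass
class Population:
    """A set of individuals sharing one marker map.

    ``gmap`` holds one row per mapped locus (``marker``, ``chrom``,
    ``pos_cm``), sorted by chromosome then position.
    """

    individuals: list[Individual]
    gmap: pd.DataFrame
    true_bv: pd.Series | None = None

    def __post_init__(self) -> None:
        n_loci = len(self.gmap)
        for ind in self.individuals:
            if ind.haplotypes.shape != (2, n_loci):
                raise ValueError(
                    f"individual {ind.id}: haplotype shape {ind.haplotypes.shape} "
                    f"does not match map with {n_loci} loci"
                )
            if ind.generation not in _GEN_INDEX:
                raise ValueError(f"unknown generation label {ind.generation!r}")

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def of_generation(self, gen: str) -> list[Individual]:
        return [ind for ind in self.individuals if ind.generation == gen]

    def latest_generation(self) -> str:
        return max((ind.generation for ind in self.individuals), key=_GEN_INDEX.get)

    def lineage_table(self) -> pd.DataFrame:
        rows = [
            (ind.id, ind.lineage, ind.generation)
            for ind in self.individuals
            if ind.lineage is not None
        ]
        return pd.DataFrame(rows, columns=["line", "lineage", "generation"])

    def _hap_stack(self, individuals: Iterable[Individual]) -> np.ndarray:
        return np.stack([ind.haplotypes for ind in individuals])

    def genotype_classes(self, generation: str | None = None) -> pd.DataFrame:
        """Per-line genotype classes 'AA', 'AB', 'BB' (lines x loci)."""
        inds = self.individuals if generation is None else self.of_generation(generation)
        haps = self._hap_stack(inds)  # (n, 2, L)
        b_count = haps.sum(axis=1)  # 0, 1, 2 copies of allele B
        classes = np.array(["AA", "AB", "BB"])[b_count]
        return pd.DataFrame(
            classes, index=[i.id for i in inds], columns=self.gmap["marker"].tolist()
        )

    def heterozygosity(self, generation: str | None = None) -> float:
        """Mean per-locus heterozygote fraction across the selected lines."""
        inds = self.individuals if generation is None else self.of_generation(generation)
        haps = self._hap_stack(inds)
        return float((haps[:, 0, :] != haps[:, 1, :]).mean())


def _check_map_sorted(gmap: pd.DataFrame) -> None:
    for _, grp in gmap.groupby("chrom", sort=False):
        pos = grp["pos_cm"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("marker map positions must be sorted within chromosome")


def _haldane(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _recombination_profile(gmap: pd.DataFrame) -> np.ndarray:
    """Per-locus switch probability: 0.5 at each chromosome start (random
    strand), Haldane r between adjacent loci otherwise."""
    _check_map_sorted(gmap)
    pos = gmap["pos_cm"].to_numpy(dtype=float)
    chrom = gmap["chrom"].to_numpy()
    r = np.empty(len(pos))
    r[0] = 0.5
    d = np.diff(pos)
    same = chrom[1:] == chrom[:-1]
    r[1:] = np.where(same, _haldane(d), 0.5)
    return r


def _gametes(
    parent: np.ndarray, switch_probs: np.ndarray, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw ``n`` gametes from one phased parent. Returns (n, L) uint8."""
    switches = rng.random((n, len(switch_probs))) < switch_probs
    strand = np.cumsum(switches, axis=1) % 2  # 0/1 index into parent haplotypes
    return np.where(strand == 0, parent[0], parent[1]).astype(np.uint8)


def meiosis(
    parent: np.ndarray, gmap: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a phased parent genotype under Haldane's map function.

    Parameters
    ----------
    parent : (2, n_loci) array of alleles in {0, 1}
    gmap : marker map sorted by chromosome then position
    rng : numpy Generator
    """
    parent = np.asarray(parent)
    if parent.shape != (2, len(gmap)):
        raise ValueError("parent haplotypes do not match the map")
    return _gametes(parent, _recombination_profile(gmap), rng, 1)[0]


# ---------------------------------------------------------------------------
# crossing and advancement


def _random_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(config.n_chromosomes):
        chrom = f"C{c + 1:02d}"
        pos = np.sort(rng.uniform(0.0, config.chrom_length, size=config.n_markers))
        for j, p in enumerate(pos):
            rows.append((f"{chrom}_M{j + 1:03d}", chrom, float(p)))
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm"])


def make_cross(config: SimConfig, rng_map: dict[str, np.random.Generator] | None = None) -> Population:
    """Cross two fully inbred, maximally divergent parents and self the F1.

    Returns a population holding P1, P2, the (fully heterozygous) F1 and
    ``config.n_f2`` F2 plants, each founding its own lineage.
    """
    streams = rng_map if rng_map is not None else rng_streams(config.seed)
    gmap = _random_map(config, streams["genome"])
    L = len(gmap)
    p1 = np.zeros((2, L), dtype=np.uint8)
    p2 = np.ones((2, L), dtype=np.uint8)
    f1 = np.stack([p1[0], p2[0]])

    individuals = [
        Individual("P1", "P1", None, p1),
        Individual("P2", "P2", None, p2),
        Individual("F1", "F1", None, f1),
    ]
    probs = _recombination_profile(gmap)
    gam = _gametes(f1, probs, streams["meiosis"], 2 * config.n_f2)
    for i in range(config.n_f2):
        lineage = f"L{i + 1:03d}"
        haps = np.stack([gam[2 * i], gam[2 * i + 1]])
        individuals.append(Individual(f"F2_{i + 1:03d}", "F2", lineage, haps))
    return Population(individuals, gmap)


def _self(
    parent: Individual,
    probs: np.ndarray,
    rng: np.random.Generator,
    new_id: str,
    gen: str,
) -> Individual:
    gam = _gametes(parent.haplotypes, probs, rng, 2)
    return Individual(new_id, gen, parent.lineage, np.stack([gam[0], gam[1]]))


def advance(
    pop: Population,
    scheme: str,
    to_generation: str,
    sibs_per_family: int = 8,
    rng: np.random.Generator | None = None,
) -> Population:
    """Advance the latest generation of ``pop`` by repeated selfing.

    ``scheme='ssd'`` takes one selfed seed per line per generation
    (single-seed descent), preserving the number of lines and their
    lineage labels.  ``scheme='self_bulk'`` produces
    ``sibs_per_family`` selfed progeny per line on the first step
    (an F3 family per F2 plant) and one per line thereafter (bulk
    maintenance toward the F4).
    """
    if scheme not in ("ssd", "self_bulk"):
        raise ValueError(f"unknown advancement scheme {scheme!r}")
    if to_generation not in _GEN_INDEX or not to_generation.startswith("F"):
        raise ValueError(f"target generation {to_generation!r} not supported")
    rng = np.random.default_rng(0) if rng is None else rng
    source_gen = pop.latest_generation()
    if _GEN_INDEX[to_generation] <= _GEN_INDEX[source_gen]:
        raise ValueError(
            f"target generation {to_generation} is not after source {source_gen}"
        )
    probs = _recombination_profile(pop.gmap)
    current = pop.of_generation(source_gen)
    gen_i = _GEN_INDEX[source_gen]
    first_step = True
    while gen_i < _GEN_INDEX[to_generation]:
        gen_i += 1
        gen = GENERATIONS[gen_i]
        nxt: list[Individual] = []
        for ind in current:
            n_prog = sibs_per_family if (scheme == "self_bulk" and first_step) else 1
            for s in range(n_prog):
                suffix = f"{ind.id}:{gen}" if n_prog == 1 else f"{ind.id}:{gen}.{s + 1}"
                nxt.append(_self(ind, probs, rng, suffix, gen))
        current = nxt
        first_step = False
    return Population(current, pop.gmap)


def make_ril_population(
    f2_pop: Population,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    extra_lineages: Sequence[str] | None = None,
) -> Population:
    """Derive ``config.n_ril`` F7 RILs from the F2 by single-seed descent.

    One F3 seed is taken per F2 lineage; if ``n_ril`` exceeds the number
    of lineages, the extra RILs come from additional F3 seeds of
    lineages sampled uniformly without replacement (or from
    ``extra_lineages`` if given), mirroring a population enlarged by
    selecting further single seeds from F3 plants.  Lineage labels are
    preserved, so several RILs may share a lineage.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    f2 = f2_pop.of_generation("F2")
    by_lineage = {ind.lineage: ind for ind in f2}
    lineages = list(by_lineage)
    n_extra = config.n_ril - len(lineages)
    if n_extra < 0:
        chosen = list(rng.choice(lineages, size=config.n_ril, replace=False))
        order = [by_lineage[l] for l in chosen]
        extra: list[str] = []
    else:
        order = [by_lineage[l] for l in lineages]
        if extra_lineages is not None:
            extra = list(extra_lineages)
            if len(extra) != n_extra:
                raise ValueError(
                    f"extra_lineages must name {n_extra} lineages, got {len(extra)}"
                )
        else:
            replace = n_extra > len(lineages)
            extra = list(rng.choice(lineages, size=n_extra, replace=replace))
    probs = _recombination_profile(f2_pop.gmap)

    # F3 founders of each RIL, then SSD to F7
    founders = [(ind, ind.lineage) for ind in order] + [
        (by_lineage[l], l) for l in extra
    ]
    rils: list[Individual] = []
    for i, (f2_ind, lineage) in enumerate(founders):
        line = _self(f2_ind, probs, rng, f"RIL_{i + 1:04d}", "F3")
        for gen in ("F4", "F5", "F6", "F7"):
            line = _self(line, probs, rng, line.id, gen)
        line.id = f"RIL_{i + 1:04d}"
        rils.append(line)
    return Population(rils, f2_pop.gmap)


# ---------------------------------------------------------------------------
# marker ascertainment


def ascertain_markers(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    marker_map: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score the population's loci as a mixed dominant/codominant panel.

    Each locus is assigned a type (dominant with probability
    ``prop_dominant``).  Codominant loci report all three classes.  A
    dominant locus cannot separate the heterozygote from one homozygote:
    its detectable phase is drawn once per locus and fixed thereafter,
    collapsing 'AB' with either 'AA' (phase A) or 'BB' (phase B).

    Returns ``(calls, marker_map)`` where ``calls`` is a lines x markers
    table of class strings ('AA', 'AB', 'BB', 'AA/AB', 'AB/BB') and
    ``marker_map`` extends the population map with ``type`` and
    ``dominant_phase`` columns.  Pass a previously returned
    ``marker_map`` to score another population on the same panel.
    """
    if marker_map is None:
        rng = np.random.default_rng(config.seed) if rng is None else rng
        gmap = pop.gmap.copy()
        is_dom = rng.random(len(gmap)) < config.prop_dominant
        gmap["type"] = np.where(is_dom, "dominant", "codominant")
        phase = np.where(rng.integers(0, 2, size=len(gmap)) == 0, "A", "B")
        gmap["dominant_phase"] = np.where(is_dom, phase, "")
    else:
        gmap = marker_map
        if not gmap["marker"].tolist() == pop.gmap["marker"].tolist():
            raise ValueError("marker_map does not match the population map")

    classes = pop.genotype_classes()
    calls = classes.copy()
    dom = gmap["type"].to_numpy() == "dominant"
    phase = gmap["dominant_phase"].to_numpy()
    vals = calls.to_numpy(dtype=object)
    for j in np.flatnonzero(dom):
        if phase[j] == "A":  # heterozygote indistinguishable from AA
            col = vals[:, j]
            col[np.isin(col, ["AA", "AB"])] = "AA/AB"
        else:  # indistinguishable from BB
            col = vals[:, j]
            col[np.isin(col, ["AB", "BB"])] = "AB/BB"
    calls = pd.DataFrame(vals, index=classes.index, columns=classes.columns)
    return calls, gmap


def generation_panels(
    marker_map: pd.DataFrame, overlap: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Split the marker panel between two genotyping generations.

    A fraction ``overlap`` of markers is common to both panels; the
    remainder is divided evenly into markers private to each panel.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must lie in [0, 1], got {overlap!r}")
    markers = marker_map["marker"].to_numpy()
    if overlap >= 1.0:
        return list(markers), list(markers)
    m = len(markers)
    n_common = int(round(overlap * m))
    perm = rng.permutation(m)
    common = set(markers[perm[:n_common]])
    rest = markers[perm[n_common:]]
    half = len(rest) // 2
    panel_a = sorted(common | set(rest[:half]))
    panel_b = sorted(common | set(rest[half:]))
    order = {mk: i for i, mk in enumerate(markers)}
    return sorted(panel_a, key=order.get), sorted(panel_b, key=order.get)


# ---------------------------------------------------------------------------
# traits


@dataclasses.dataclass
class TraitModel:
    """Additive architecture: QTL loci with effects, optional major gene."""

    qtl_index: np.ndarray  # locus indices into the map
    effects: np.ndarray  # allele-substitution effects, trait units
    major_index: int | None = None
    major_effect: float = 0.0


def sample_trait_model(
    gmap: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> TraitModel:
    if config.n_qtl > len(gmap):
        raise ValueError(
            f"n_qtl={config.n_qtl} exceeds the {len(gmap)} mapped loci"
        )
    qtl = np.sort(rng.choice(len(gmap), size=config.n_qtl, replace=False))
    effects = rng.normal(0.0, config.qtl_effect_scale, size=config.n_qtl)
    major_index = None
    major_effect = 0.0
    if config.major_gene is not None:
        chrom, pos, major_effect = config.major_gene
        if isinstance(chrom, int):
            chrom = f"C{chrom:02d}"
        on_chrom = gmap.index[gmap["chrom"] == chrom]
        if len(on_chrom) == 0:
            raise ValueError(f"major_gene chromosome {chrom!r} not in the map")
        dist = (gmap.loc[on_chrom, "pos_cm"] - float(pos)).abs()
        major_index = int(dist.idxmin())
    return TraitModel(qtl, effects, major_index, float(major_effect))


def breeding_values(pop: Population, model: TraitModel) -> pd.Series:
    """True additive breeding values: sum over QTL of (A-dosage - 1) x effect."""
    haps = np.stack([ind.haplotypes for ind in pop.individuals]).astype(np.int64)
    a_dosage = 2 - haps.sum(axis=1)  # copies of allele A, 0..2
    score = (a_dosage[:, model.qtl_index] - 1) @ model.effects
    if model.major_index is not None:
        score = score + (a_dosage[:, model.major_index] - 1) * model.major_effect
    return pd.Series(score.astype(float), index=pop.ids, name="true_bv")


def simulate_trait(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    model: TraitModel | None = None,
    trait: str = "trait",
    unit: str = "line",
    first_year: int = 2005,
) -> tuple[pd.DataFrame, TraitModel]:
    """Simulate phenotypes with known architecture and heritability.

    Phenotype per line and environment is breeding value + environment
    main effect + residual, with residual variance calibrated so that
    var(BV) / var(phenotype) equals ``config.h2`` at the analysis unit
    (the mean across environments).  Environment main effects are shared
    by all lines within a year, so they shift but never reorder lines.

    ``unit='family'`` treats each lineage as an F4-style bulk: the
    recorded value is the family mean of per-sib values plus a shared
    plot error, and the returned table is keyed by lineage id.

    With ``h2=0`` the trait is pure noise (no genetic term, unit residual
    variance).  Returns ``(phenotypes, model)`` where phenotypes has
    columns line, trait, year, environment, value.
    """
    if model is None:
        model = sample_trait_model(pop.gmap, config, rng)
    bv = breeding_values(pop, model)
    pop.true_bv = bv

    f_env = config.env_var_fraction
    n_env = config.n_environments
    if config.h2 == 0.0 and f_env >= 1.0:
        raise ValueError(
            "h2=0 with env_var_fraction=1 leaves zero residual variance; "
            "a pure-noise trait needs a residual"
        )

    if unit == "family":
        groups = pd.Series(
            {ind.id: ind.lineage for ind in pop.individuals}, name="lineage"
        )
        fam_bv = bv.groupby(groups).mean()
        units = fam_bv.index.to_numpy()
        genetic = fam_bv.to_numpy()
    elif unit == "line":
        units = np.array(pop.ids)
        genetic = bv.to_numpy()
    else:
        raise ValueError(f"unknown analysis unit {unit!r}")

    if config.h2 == 0.0:
        genetic = np.zeros_like(genetic)
        sigma2_e_unit = 1.0
    elif config.h2 == 1.0:
        sigma2_e_unit = 0.0
    else:
        vb = float(np.var(genetic))
        if vb == 0.0:
            raise ValueError(
                "breeding values have zero variance; cannot calibrate h2 "
                f"({config.h2}) — add QTL or a major gene"
            )
        sigma2_e_unit = vb * (1.0 - config.h2) / config.h2

    # env main effect variance from the stated split of non-genetic variance
    if sigma2_e_unit > 0 and f_env < 1.0:
        sigma2_env = sigma2_e_unit * f_env / (1.0 - f_env)
    else:
        sigma2_env = 0.0

    rows = []
    env_effects = rng.normal(0.0, np.sqrt(sigma2_env), size=n_env)
    for e in range(n_env):
        year = first_year + e
        # per-observation residual so the mean over n_env hits the unit variance
        sd_obs = np.sqrt(sigma2_e_unit * n_env)
        if unit == "family":
            # family mean of sib noise plus a shared plot error, split evenly
            sib_noise = rng.normal(
                0.0,
                np.sqrt(sigma2_e_unit * n_env * config.sibs_per_family / 2.0),
                size=(len(units), config.sibs_per_family),
            ).mean(axis=1)
            plot = rng.normal(0.0, np.sqrt(sigma2_e_unit * n_env / 2.0), size=len(units))
            resid = sib_noise + plot
        else:
            resid = rng.normal(0.0, sd_obs, size=len(units))
        values = genetic + env_effects[e] + resid
        for u, v in zip(units, values):
            rows.append((u, trait, year, f"E{e + 1}", float(v)))
    pheno = pd.DataFrame(rows, columns=["line", "trait", "year", "environment", "value"])
    return pheno, model


def phenotype_means(pheno: pd.DataFrame, trait: str | None = None) -> pd.Series:
    """Per-line phenotypic means across years/environments (the analysis unit)."""
    df = pheno if trait is None else pheno[pheno["trait"] == trait]
    return df.groupby("line")["value"].mean()


# ---------------------------------------------------------------------------
# missingness


def mask_genotypes(
    gm: pd.DataFrame, rate: float, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank a uniform random subset of observed cells.

    Exactly ``floor(rate * n_cells)`` observed cells are set missing.
    Returns the masked matrix and a (line, marker) index of the masked
    cells for later scoring.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must lie in [0, 1), got {rate!r}")
    values = gm.to_numpy(dtype=float, copy=True)
    n_mask = int(np.floor(rate * values.size))
    obs_r, obs_c = np.nonzero(~np.isnan(values))
    if n_mask > len(obs_r):
        raise ValueError(
            f"cannot mask {n_mask} cells: only {len(obs_r)} observed cells"
        )
    mask_rows: list[tuple[str, str]] = []
    if n_mask > 0:
        pick = rng.choice(len(obs_r), size=n_mask, replace=False)
        values[obs_r[pick], obs_c[pick]] = np.nan
        mask_rows = [
            (gm.index[r], gm.columns[c]) for r, c in zip(obs_r[pick], obs_c[pick])
        ]
    masked = pd.DataFrame(values, index=gm.index, columns=gm.columns)
    return masked, pd.DataFrame(mask_rows, columns=["line", "marker"])


# ---------------------------------------------------------------------------
# end-to-end dataset


@dataclasses.dataclass
class SimulatedDataset:
    """Everything the downstream pipeline consumes, from one root seed."""

    config: SimConfig
    f2: Population
    ril: Population
    marker_map: pd.DataFrame  # with type / dominant_phase
    calls_f2: pd.DataFrame  # F2 lines x F2 panel, class strings
    calls_ril: pd.DataFrame
    genotypes_f2: pd.DataFrame  # encoded numeric, missing as NaN
    genotypes_ril: pd.DataFrame
    phenotypes: pd.DataFrame  # early + RIL rows
    lineage: pd.DataFrame  # line, lineage, generation
    trait_model: TraitModel

    @property
    def common_markers(self) -> list[str]:
        cols = set(self.genotypes_ril.columns)
        return [m for m in self.genotypes_f2.columns if m in cols]


def simulate_type_separated(
    config: SimConfig, driver_type: str = "dominant"
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """F2 dataset whose trait is driven by one marker type only.

    Chromosomes are typed wholesale — the first half dominant, the rest
    codominant — so the two marker classes are mutually unlinked, and
    every QTL lands on a chromosome of ``driver_type``.  This isolates
    which marker class carries the signal, the construction used to
    check that the DiPR weight scan recovers the informative kernel.

    Returns ``(y, gm, gmap, genotypes)`` with y the per-line phenotype
    means and gm the encoded complete genotype matrix.
    """
    from . import markers as _markers

    if driver_type not in ("dominant", "codominant"):
        raise ValueError(f"driver_type must be dominant/codominant, got {driver_type!r}")
    streams = rng_streams(config.seed)
    cross = make_cross(config, streams)
    f2 = Population(cross.of_generation("F2"), cross.gmap)
    gmap = cross.gmap.copy()
    chroms = gmap["chrom"].unique()
    dom_mask = gmap["chrom"].isin(chroms[: len(chroms) // 2]).to_numpy()
    gmap["type"] = np.where(dom_mask, "dominant", "codominant")
    rng = streams["markers"]
    phase = np.where(rng.integers(0, 2, size=len(gmap)) == 0, "A", "B")
    gmap["dominant_phase"] = np.where(dom_mask, phase, "")
    calls, _ = ascertain_markers(f2, config, marker_map=gmap)
    gm = _markers.encode(calls, gmap)

    driver_idx = np.flatnonzero(dom_mask if driver_type == "dominant" else ~dom_mask)
    if config.n_qtl > len(driver_idx):
        raise ValueError(
            f"n_qtl={config.n_qtl} exceeds the {len(driver_idx)} {driver_type} loci"
        )
    qtl = np.sort(streams["trait"].choice(driver_idx, size=config.n_qtl, replace=False))
    model = TraitModel(qtl, streams["trait"].normal(0.0, config.qtl_effect_scale, config.n_qtl))
    pheno, _ = simulate_trait(f2, config, streams["trait"], model=model)
    y = phenotype_means(pheno)
    return y, gm, gmap, pheno


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Simulate the full study design from one seed.

    Cross two inbreds, genotype the F2 on a mixed panel, derive F7 RILs
    by SSD and genotype them on a (possibly partially overlapping)
    panel, simulate an additive trait on both generations across
    ``n_environments`` years, and blank genotype calls at
    ``missing_rate``.
    """
    from . import markers as _markers  # deferred to avoid a cycle

    streams = rng_streams(config.seed)
    cross = make_cross(config, streams)
    ril = make_ril_population(cross, config, streams["meiosis"])

    f2_only = Population(cross.of_generation("F2"), cross.gmap)
    calls_f2_full, marker_map = ascertain_markers(f2_only, config, streams["markers"])
    calls_ril_full, _ = ascertain_markers(ril, config, marker_map=marker_map)

    panel_f2, panel_ril = generation_panels(
        marker_map, config.common_marker_overlap, streams["markers"]
    )
    calls_f2 = calls_f2_full[panel_f2]
    calls_ril = calls_ril_full[panel_ril]

    geno_f2 = _markers.encode(calls_f2, marker_map)
    geno_ril = _markers.encode(calls_ril, marker_map)
    if config.missing_rate > 0:
        geno_f2, _ = mask_genotypes(geno_f2, config.missing_rate, streams["masking"])
        geno_ril, _ = mask_genotypes(geno_ril, config.missing_rate, streams["masking"])

    model = sample_trait_model(cross.gmap, config, streams["trait"])
    pheno_f2, _ = simulate_trait(
        f2_only, config, streams["trait"], model=model, first_year=2005
    )
    pheno_ril, _ = simulate_trait(
        ril, config, streams["trait"], model=model, first_year=2010
    )
    pheno = pd.concat([pheno_f2, pheno_ril], ignore_index=True)

    lineage = pd.concat(
        [f2_only.lineage_table(), ril.lineage_table()], ignore_index=True
    )
    return SimulatedDataset(
        config=config,
        f2=f2_only,
        ril=ril,
        marker_map=marker_map,
        calls_f2=calls_f2,
        calls_ril=calls_ril,
        genotypes_f2=geno_f2,
        genotypes_ril=geno_ril,
        phenotypes=pheno,
        lineage=lineage,
        trait_model=model,
    )
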