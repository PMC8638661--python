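"""Evaluation designs for within-cross genomic prediction.

Two families of design:

* within-generation Monte-Carlo cross-validation — repeated random
  80/20 splits of the phenotyped lines, with optional stratification on
  the major dwarfing-gene (Dw6-style) classes, each class evaluated
  independently only when its training portion exceeds a minimum size;
* between-generation lineage k-fold sampling — per replicate a
  fraction 1/k of the F2 lineages is drawn as the genotyped+phenotyped
  training set, mimicking a breeder who invested in genotyping only
  part of the early generation; all RILs are predicted, and accuracy is
  reported separately for RILs inside (within-family) and outside
  (between-family) the sampled lineages.

Accuracies are pairwise Pearson correlations; replicate correlations
are averaged on Fisher's Z scale (atanh) and back-transformed, since Z
is approximately normal where r is not.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import fit_gblup

__all__ = [
    "CVScheme",
    "AccuracyReport",
    "pearson",
    "fisher_mean",
    "make_partitions",
    "gblup_predictor",
    "mccv_within",
    "lineage_kfold_between",
    "stratify_dw6",
    "phenotypic_proxy",
]

# a predictor maps (training phenotypes, test line ids) -> GEBVs for the test ids
Predictor = Callable[[pd.Series, Sequence[str]], pd.Series]


@dataclasses.dataclass(frozen=True)
class CVScheme:
    """Configuration of one evaluation design."""

    kind: str = "mccv_within"  # or "lineage_kfold"
    test_fraction: float = 0.2
    k: int | None = None
    replicates: int = 100
    seed: int = 0
    stratify_dw6: bool = False
    min_stratum_train: int = 30

    def __post_init__(self) -> None:
        if self.kind not in ("mccv_within", "lineage_kfold"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "lineage_kfold":
            if self.k not in (2, 3, 4, 5):
                raise ValueError(f"k must be one of 2, 3, 4, 5; got {self.k!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(
                f"test_fraction must lie in (0, 1), got {self.test_fraction!r}"
            )
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates!r}")


@dataclasses.dataclass
class AccuracyReport:
    """Per-replicate correlations and their Fisher-Z aggregate."""

    replicate_r: list[float]
    aggregate: float
    n_eff: float  # mean evaluated lines per replicate
    n_excluded: int = 0  # replicates dropped (constant vectors / too few pairs)
    strata: dict[str, "AccuracyReport | None"] | None = None


def pearson(x, y) -> float:
    """Product-moment correlation; raises on <3 pairs or a constant vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need at least 3 paired values, got {len(x)}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float((xc @ yc) / (sx * sy))


def fisher_mean(rs: Sequence[float]) -> float:
    """Back-transformed mean of correlations on Fisher's Z scale.

    r_bar = tanh(mean(atanh(r_i))); values at +/-1 are clamped to
    +/-(1 - 1e-12) before the transform.
    """
    rs = np.asarray(list(rs), dtype=float)
    if rs.size == 0:
        raise ValueError("cannot aggregate an empty list of correlations")
    if np.any(np.abs(rs) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    clipped = np.clip(rs, -1.0 + 1e-12, 1.0 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(clipped))))


def _aggregate(rs: list[float], n_eval: list[int], n_excluded: int) -> AccuracyReport:
    agg = fisher_mean(rs) if rs else float("nan")
    n_eff = float(np.mean(n_eval)) if n_eval else 0.0
    return AccuracyReport(rs, agg, n_eff, n_excluded)


def make_partitions(
    ids: Sequence[str], scheme: CVScheme
) -> list[tuple[list[str], list[str]]]:
    """Replicate train/test splits, fully determined by the scheme seed.

    Each replicate draws ``round(n * test_fraction)`` test lines without
    replacement; the rest train.  Splits are disjoint within a
    replicate by construction.
    """
    ids = list(ids)
    n = len(ids)
    n_test = max(1, int(round(n * scheme.test_fraction)))
    if n - n_test < 2:
        raise ValueError(
            f"too few lines ({n}) for a {scheme.test_fraction:.0%} test split"
        )
    rng = np.random.default_rng(scheme.seed)
    parts = []
    for _ in range(scheme.replicates):
        perm = rng.permutation(n)
        test = [ids[i] for i in perm[:n_test]]
        train = [ids[i] for i in perm[n_test:]]
        parts.append((train, test))
    return parts


def gblup_predictor(K: pd.DataFrame) -> Predictor:
    """Predictor factory: GBLUP on a fixed precomputed kernel."""

    def _predict(y_train: pd.Series, test_ids: Sequence[str]) -> pd.Series:
        lines = list(y_train.index) + [t for t in test_ids if t not in y_train.index]
        K_sub = K.loc[lines, lines]
        fit = fit_gblup(y_train.reindex(K_sub.index), K_sub)
        return fit.u.loc[list(test_ids)]

    return _predict


def mccv_within(
    y: pd.Series,
    predictor: Predictor,
    scheme: CVScheme,
    classes: pd.Series | None = None,
) -> AccuracyReport:
    """Within-generation Monte-Carlo cross-validation.

    Each replicate holds out a random ``test_fraction`` of the
    phenotyped lines, trains the predictor on the rest, and records the
    Pearson correlation between observed phenotypes and GEBVs on the
    held-out lines; replicates aggregate by Fisher-Z mean.  Replicates
    with a constant vector or fewer than 3 evaluable pairs are flagged
    and excluded.

    With ``scheme.stratify_dw6`` and a ``classes`` labeling (e.g. Tall /
    Dwarf), the same design is additionally run inside each class, but
    only where the class's training portion exceeds
    ``scheme.min_stratum_train`` lines; otherwise that stratum is
    reported as not evaluated (None).
    """
    y = y.dropna()
    report = _mccv_single(y, predictor, scheme)
    if scheme.stratify_dw6:
        if classes is None:
            raise ValueError("stratify_dw6 requires class labels")
        strata: dict[str, AccuracyReport | None] = {"All": report}
        for label in sorted(classes.dropna().unique()):
            members = y.index[y.index.isin(classes.index[classes == label])]
            n_train = len(members) - max(1, int(round(len(members) * scheme.test_fraction)))
            if n_train > scheme.min_stratum_train:
                strata[label] = _mccv_single(y.loc[members], predictor, scheme)
            else:
                strata[label] = None
        report = dataclasses.replace(report, strata=strata)
    return report


def _mccv_single(y: pd.Series, predictor: Predictor, scheme: CVScheme) -> AccuracyReport:
    parts = make_partitions(list(y.index), scheme)
    rs: list[float] = []
    n_eval: list[int] = []
    excluded = 0
    for train, test in parts:
        pred = predictor(y.loc[train], test)
        try:
            rs.append(pearson(y.loc[test].to_numpy(), pred.to_numpy()))
            n_eval.append(len(test))
        except ValueError:
            excluded += 1
    return _aggregate(rs, n_eval, excluded)


def lineage_kfold_between(
    y_early: pd.Series,
    early_lineage: pd.Series,
    y_ril: pd.Series,
    ril_lineage: pd.Series,
    predictor: Predictor,
    scheme: CVScheme,
) -> AccuracyReport:
    """Between-generation prediction from a sampled subset of lineages.

    Per replicate, ``ceil(n_lineages / k)`` F2 lineages are drawn
    without replacement; early-generation lines of those lineages train
    the model (simulating a breeder who genotyped and phenotyped 1/k of
    the early generation), all RILs are predicted, and accuracy is
    recorded separately for RILs descending from sampled lineages
    (within-family) and from unsampled ones (between-family).  The two
    line sets partition the RILs each replicate.  Aggregation is
    Fisher-Z over replicates, per stratum.
    """
    if scheme.k not in (2, 3, 4, 5):
        raise ValueError(f"k must be one of 2, 3, 4, 5; got {scheme.k!r}")
    y_early = y_early.dropna()
    y_ril = y_ril.dropna()
    missing = y_ril.index[~y_ril.index.isin(ril_lineage.index)]
    if len(missing):
        raise ValueError(f"RILs without a lineage assignment: {list(missing)[:5]}")
    lineages = sorted(early_lineage.loc[early_lineage.index.isin(y_early.index)].unique())
    n_sample = math.ceil(len(lineages) / scheme.k)
    rng = np.random.default_rng(scheme.seed)

    within_rs: list[float] = []
    between_rs: list[float] = []
    n_within: list[int] = []
    n_between: list[int] = []
    excl_w = excl_b = 0
    for _ in range(scheme.replicates):
        sampled = set(rng.choice(lineages, size=n_sample, replace=False))
        train_ids = [l for l in y_early.index if early_lineage.get(l) in sampled]
        ril_ids = list(y_ril.index)
        pred = predictor(y_early.loc[train_ids], ril_ids)
        in_fam = [r for r in ril_ids if ril_lineage.loc[r] in sampled]
        out_fam = [r for r in ril_ids if ril_lineage.loc[r] not in sampled]
        for subset, rs, ns, which in (
            (in_fam, within_rs, n_within, "w"),
            (out_fam, between_rs, n_between, "b"),
        ):
            try:
                rs.append(pearson(y_ril.loc[subset].to_numpy(), pred.loc[subset].to_numpy()))
                ns.append(len(subset))
            except ValueError:
                if which == "w":
                    excl_w += 1
                else:
                    excl_b += 1

    within = _aggregate(within_rs, n_within, excl_w)
    between = _aggregate(between_rs, n_between, excl_b)
    overall = AccuracyReport(
        replicate_r=within.replicate_r + between.replicate_r,
        aggregate=fisher_mean(within.replicate_r + between.replicate_r)
        if (within.replicate_r or between.replicate_r)
        else float("nan"),
        n_eff=float(np.mean(n_within + n_between)) if (n_within or n_between) else 0.0,
        n_excluded=excl_w + excl_b,
        strata={"within_family": within, "between_family": between},
    )
    return overall


def stratify_dw6(
    gm: pd.DataFrame,
    dw6_marker: str,
    positive_class: str = "Tall",
    het_class: str = "Dwarf",
) -> pd.Series:
    """Tall/Dwarf class labels from the code sign at a designated marker.

    Positive codes map to ``positive_class``, negative to the other
    class; heterozygotes (code 0 at a codominant marker) join
    ``het_class`` — by default Dwarf, the dominant phenotype of a
    Dw6-style dwarfing gene.
    """
    if dw6_marker not in gm.columns:
        raise ValueError(f"marker {dw6_marker!r} not in the genotype matrix")
    codes = gm[dw6_marker]
    if codes.isna().any():
        bad = list(codes.index[codes.isna()])[:5]
        raise ValueError(f"missing {dw6_marker!r} codes (impute first): {bad}")
    other = "Dwarf" if positive_class == "Tall" else "Tall"
    labels = np.where(
        codes > 0, positive_class, np.where(codes < 0, other, het_class)
    )
    return pd.Series(labels, index=gm.index, name="dw6_class")


def phenotypic_proxy(
    early_pheno: pd.Series,
    ril_pheno: pd.Series,
    early_lineage: pd.Series,
    ril_lineage: pd.Series,
) -> float:
    """Early-vs-late phenotypic correlation at the lineage level.

    Correlates the mean early-generation phenotype of each lineage with
    the mean phenotype of its RILs — a proxy for the accuracy of
    selecting on early phenotype alone.
    """
    early = early_pheno.dropna().groupby(early_lineage).mean()
    ril = ril_pheno.dropna().groupby(ril_lineage).mean()
    shared = early.index.intersection(ril.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 lineages with both records, got {len(shared)}")
    return pearson(early.loc[shared].to_numpy(), ril.loc[shared].to_numpy())
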