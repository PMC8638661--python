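"""Mixed-marker encoding, imputation, LD thinning and kinship.

Genotype calls from dominant (presence/absence) and codominant assays
are integrated into one numeric matrix: codominant classes score
AA: 1, AB: 0, BB: -1, while a dominant marker's two distinguishable
classes receive half scores (+0.5 for the class containing AA, -0.5 for
the class containing BB) to reflect their uncertainty, akin to an
imputed marker.  From the (complete) matrix, per-type additive
relationship matrices are built and may be combined with weights
(w, 1 - w) for differentially penalized ridge regression.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CODOMINANT_CODES",
    "DOMINANT_CODES",
    "encode",
    "decode",
    "MarkerImputer",
    "impute",
    "imputation_chisq",
    "thin",
    "kinship",
    "combine",
    "check_kinship",
]

CODOMINANT_CODES = {"AA": 1.0, "AB": 0.0, "BB": -1.0}
# class containing AA scores +0.5; class containing BB scores -0.5
DOMINANT_CODES = {"AA/AB": 0.5, "AA": 0.5, "AB/BB": -0.5, "BB": -0.5}
_MISSING_STRINGS = {"", "NA", "NaN", "nan", None}

LEGAL_CODES = {
    "codominant": np.array([1.0, 0.0, -1.0]),
    "dominant": np.array([0.5, -0.5]),
}


def _marker_types(gmap: pd.DataFrame, markers: pd.Index) -> pd.Series:
    types = gmap.set_index("marker")["type"]
    missing = [m for m in markers if m not in types.index]
    if missing:
        raise ValueError(f"markers missing from the map: {missing[:5]}")
    return types.loc[markers]


def encode(calls: pd.DataFrame, gmap: pd.DataFrame) -> pd.DataFrame:
    """Numeric scores from categorical genotype classes.

    Codominant: AA -> 1, AB -> 0, BB -> -1.  Dominant: the collapsed
    class containing AA ('AA/AB' or bare 'AA') -> 0.5, the class
    containing BB -> -0.5.  Missing calls stay missing (NaN).  An
    illegal class for a marker's type raises, naming marker and line.
    """
    types = _marker_types(gmap, calls.columns)
    out = np.full(calls.shape, np.nan)
    vals = calls.to_numpy(dtype=object)
    for j, marker in enumerate(calls.columns):
        table = CODOMINANT_CODES if types.iloc[j] == "codominant" else DOMINANT_CODES
        for i in range(vals.shape[0]):
            v = vals[i, j]
            if v in _MISSING_STRINGS or (isinstance(v, float) and np.isnan(v)):
                continue
            try:
                out[i, j] = table[v]
            except KeyError:
                raise ValueError(
                    f"illegal {types.iloc[j]} class {v!r} at marker "
                    f"{marker!r}, line {calls.index[i]!r}"
                ) from None
    return pd.DataFrame(out, index=calls.index, columns=calls.columns)


def decode(gm: pd.DataFrame, gmap: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`encode` on non-missing cells."""
    types = _marker_types(gmap, gm.columns)
    inv_cod = {v: k for k, v in CODOMINANT_CODES.items()}
    inv_dom = {0.5: "AA/AB", -0.5: "AB/BB"}
    out = np.full(gm.shape, None, dtype=object)
    vals = gm.to_numpy(dtype=float)
    for j in range(vals.shape[1]):
        table = inv_cod if types.iloc[j] == "codominant" else inv_dom
        for i in range(vals.shape[0]):
            v = vals[i, j]
            if np.isnan(v):
                continue
            out[i, j] = table[v]
    return pd.DataFrame(out, index=gm.index, columns=gm.columns)


def _round_to_legal(values: np.ndarray, legal: np.ndarray) -> np.ndarray:
    idx = np.argmin(np.abs(values[:, None] - legal[None, :]), axis=1)
    return legal[idx]


class MarkerImputer:
    """Impute missing genotype codes, sklearn-transformer style.

    ``method='column_mean'`` fills each cell with its marker's observed
    mean — deterministic, the default.  ``method='iterative_nonparametric'``
    runs a missForest-style loop: starting from mean fill, each
    incomplete marker is regressed on all others with a random forest,
    sweeping markers from least to most missing, until the change in
    imputed values stops decreasing; imputed cells are finally rounded
    to the nearest legal code for the marker's type.
    """

    def __init__(
        self,
        method: str = "column_mean",
        gmap: pd.DataFrame | None = None,
        n_trees: int = 100,
        max_iter: int = 10,
        random_state: int | np.random.Generator | None = 0,
    ):
        if method not in ("column_mean", "iterative_nonparametric"):
            raise ValueError(f"unknown imputation method {method!r}")
        self.method = method
        self.gmap = gmap
        self.n_trees = n_trees
        self.max_iter = max_iter
        self.random_state = random_state

    def fit_transform(self, gm: pd.DataFrame) -> pd.DataFrame:
        vals = gm.to_numpy(dtype=float, copy=True)
        miss = np.isnan(vals)
        all_missing = miss.all(axis=0)
        if all_missing.any():
            bad = list(gm.columns[all_missing])[:5]
            raise ValueError(f"markers with no observed values: {bad}")
        if not miss.any():
            return gm.copy()
        col_means = np.nanmean(vals, axis=0)
        filled = np.where(miss, col_means[None, :], vals)
        if self.method == "column_mean":
            return pd.DataFrame(filled, index=gm.index, columns=gm.columns)
        return self._iterative(gm, vals, miss, filled)

    # missForest loop with a random-forest base learner
    def _iterative(
        self,
        gm: pd.DataFrame,
        vals: np.ndarray,
        miss: np.ndarray,
        filled: np.ndarray,
    ) -> pd.DataFrame:
        from sklearn.ensemble import RandomForestRegressor

        seed = self.random_state
        if isinstance(seed, np.random.Generator):
            seed = int(seed.integers(2**31 - 1))
        order = np.argsort(miss.sum(axis=0))
        incomplete = [j for j in order if miss[:, j].any()]
        prev_change = np.inf
        best = filled.copy()
        for it in range(self.max_iter):
            previous = filled.copy()
            for j in incomplete:
                obs = ~miss[:, j]
                others = np.delete(filled, j, axis=1)
                rf = RandomForestRegressor(
                    n_estimators=self.n_trees,
                    random_state=(seed or 0) + it,
                    n_jobs=1,
                )
                rf.fit(others[obs], vals[obs, j])
                filled[miss[:, j], j] = rf.predict(others[miss[:, j]])
            change = float(((filled - previous) ** 2)[miss].sum())
            if change >= prev_change:  # stopped decreasing: keep previous sweep
                filled = previous
                break
            best = filled.copy()
            prev_change = change
        filled = best
        if self.gmap is not None:
            types = _marker_types(self.gmap, gm.columns)
            for j, t in enumerate(types):
                m = miss[:, j]
                if m.any():
                    filled[m, j] = _round_to_legal(filled[m, j], LEGAL_CODES[t])
        else:
            # infer the legal codes from the observed values per marker
            for j in range(filled.shape[1]):
                m = miss[:, j]
                if m.any():
                    legal = np.unique(vals[~np.isnan(vals[:, j]), j])
                    filled[m, j] = _round_to_legal(filled[m, j], legal)
        return pd.DataFrame(filled, index=gm.index, columns=gm.columns)


def impute(
    gm: pd.DataFrame,
    method: str = "column_mean",
    rng: int | np.random.Generator | None = 0,
    gmap: pd.DataFrame | None = None,
    n_trees: int = 100,
    max_iter: int = 10,
) -> pd.DataFrame:
    """Functional wrapper over :class:`MarkerImputer`."""
    return MarkerImputer(
        method=method, gmap=gmap, n_trees=n_trees, max_iter=max_iter, random_state=rng
    ).fit_transform(gm)


def imputation_chisq(
    gm_true: pd.DataFrame,
    gm_imputed: pd.DataFrame,
    mask: pd.DataFrame,
    gmap: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Score imputation at artificially removed cells.

    Returns ``(error_rate, chi2)``: the fraction of masked cells whose
    imputed class (rounded to the marker's nearest legal code) differs
    from the truth, and a chi-squared statistic comparing the class
    frequency spectrum of imputed vs true values over the masked cells.
    """
    if len(mask) == 0:
        raise ValueError("mask is empty: nothing to score")
    types = None
    if gmap is not None:
        types = gmap.set_index("marker")["type"]
    truth, imput = [], []
    for line, marker in mask.itertuples(index=False):
        t = float(gm_true.at[line, marker])
        v = float(gm_imputed.at[line, marker])
        if types is not None:
            legal = LEGAL_CODES[types.loc[marker]]
        else:
            col = gm_true[marker].dropna().to_numpy()
            legal = np.unique(col)
        truth.append(t)
        imput.append(float(_round_to_legal(np.array([v]), legal)[0]))
    truth_a = np.array(truth)
    imput_a = np.array(imput)
    error_rate = float((truth_a != imput_a).mean())
    classes = np.unique(np.concatenate([truth_a, imput_a]))
    f_true = np.array([(truth_a == c).sum() for c in classes], dtype=float)
    f_imp = np.array([(imput_a == c).sum() for c in classes], dtype=float)
    keep = f_true > 0
    if (~keep).any() and f_imp[~keep].sum() > 0:
        # imputed classes absent from truth: fold into nearest true class
        for c_idx in np.flatnonzero(~keep):
            near = np.argmin(np.abs(classes[keep] - classes[c_idx]))
            f_imp[np.flatnonzero(keep)[near]] += f_imp[c_idx]
    chi2 = float(((f_imp[keep] - f_true[keep]) ** 2 / f_true[keep]).sum())
    return error_rate, chi2


def thin(
    gm: pd.DataFrame,
    gmap: pd.DataFrame,
    r2_threshold: float = 0.90,
    scope: str = "chromosome",
) -> list[str]:
    """Greedy LD pruning in map order.

    Monomorphic markers are dropped first.  Scanning each chromosome in
    map position order (``scope='genome'`` scans the whole map), a
    marker is dropped when its squared Pearson correlation with any
    already-retained marker in scope exceeds ``r2_threshold``.
    Keep-first greedy: deterministic given input order.
    """
    if gm.isna().any().any():
        raise ValueError("thin requires a complete (imputed) matrix")
    if scope not in ("chromosome", "genome"):
        raise ValueError(f"unknown thinning scope {scope!r}")
    order = gmap.set_index("marker")
    present = [m for m in order.index if m in gm.columns]
    retained: list[str] = []
    vals = gm[present].to_numpy(dtype=float)
    sd = vals.std(axis=0)
    col_of = {m: i for i, m in enumerate(present)}

    def groups():
        if scope == "genome":
            yield present
        else:
            for _, grp in order.loc[present].groupby("chrom", sort=False):
                yield list(grp.index)

    for group in groups():
        kept_idx: list[int] = []
        for m in group:
            j = col_of[m]
            if sd[j] == 0:  # monomorphic
                continue
            x = vals[:, j]
            ok = True
            for k in kept_idx:
                r = np.corrcoef(x, vals[:, k])[0, 1]
                if r * r > r2_threshold:
                    ok = False
                    break
            if ok:
                kept_idx.append(j)
                retained.append(m)
    return retained


def kinship(gm: pd.DataFrame, markers: list[str] | None = None) -> pd.DataFrame:
    """Additive genomic relationship matrix from a complete code matrix.

    Columns are centered and K = W Wᵀ is scaled so its mean diagonal is
    1, making per-type matrices comparable in magnitude regardless of
    marker count or code range.  Dominant half scores enter exactly like
    codominant codes.
    """
    sub = gm if markers is None else gm[list(markers)]
    if sub.shape[1] == 0:
        raise ValueError("kinship requires at least one marker")
    if sub.isna().any().any():
        raise ValueError("kinship requires a complete (imputed) matrix")
    W = sub.to_numpy(dtype=float)
    W = W - W.mean(axis=0, keepdims=True)
    K = W @ W.T
    scale = np.trace(K) / K.shape[0]
    if scale <= 0:
        raise ValueError("all selected markers are monomorphic")
    K = K / scale
    K = (K + K.T) / 2.0
    out = pd.DataFrame(K, index=sub.index, columns=sub.index)
    out.attrs["normalization"] = "centered, mean diagonal 1"
    return out


def combine(K_dom: pd.DataFrame, K_cod: pd.DataFrame, w: float) -> pd.DataFrame:
    """Weighted kernel combination K(w) = w K_dom + (1 - w) K_cod.

    At w = 0 only the codominant kernel contributes; at w = 1 only the
    dominant kernel.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight w must lie in [0, 1], got {w!r}")
    if list(K_dom.index) != list(K_cod.index):
        raise ValueError("kinship matrices cover different line sets or orders")
    if w == 0.0:
        return K_cod.copy()
    if w == 1.0:
        return K_dom.copy()
    out = w * K_dom + (1.0 - w) * K_cod
    out.attrs["normalization"] = f"combined w={w}"
    return out


def check_kinship(K: pd.DataFrame, tol: float = 1e-8) -> None:
    """Validate symmetry and positive semidefiniteness (within tolerance)."""
    A = K.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("kinship matrix is not symmetric")
    ev = np.linalg.eigvalsh(A)
    if ev[0] < -tol * max(ev[-1], 1.0):
        raise ValueError(
            f"kinship matrix is not positive semidefinite (min eigenvalue {ev[0]:.3g})"
        )


def segregation_chisq(gm: pd.DataFrame, gmap: pd.DataFrame) -> tuple[float, float]:
    """Aggregate chi-square test of 1:2:1 segregation over codominant markers.

    Each codominant marker of an F2 matrix is tested against the
    Mendelian 1:2:1 expectation (individuals are independent within a
    locus); the per-locus statistics are summed, with 2 degrees of
    freedom per locus.  Returns (statistic, p-value).
    """
    types = _marker_types(gmap, gm.columns)
    cod = gm.loc[:, (types == "codominant").to_numpy()]
    if cod.shape[1] == 0:
        raise ValueError("no codominant markers to test")
    vals = cod.to_numpy(dtype=float)
    counts = np.stack([(vals == c).sum(axis=0) for c in (1.0, 0.0, -1.0)])  # 3 x L
    totals = counts.sum(axis=0)
    expected = np.array([0.25, 0.5, 0.25])[:, None] * totals[None, :]
    per_locus = ((counts - expected) ** 2 / expected).sum(axis=0)
    chi2 = float(per_locus.sum())
    p = float(stats.chi2.sf(chi2, df=2 * cod.shape[1]))
    return chi2, p
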