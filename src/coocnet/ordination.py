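"""Constrained ordination (db-RDA) and family-level enrichment tests.

db-RDA double-centers the squared Bray-Curtis dissimilarities into a Gower
matrix, takes its principal coordinates, and projects the positive-
eigenvalue coordinate space onto the constraint matrix. Constrained
inertia is the sum of canonical eigenvalues; the inertia carried by
negative eigenvalues (Bray-Curtis is non-Euclidean) is excluded from the
decomposition and reported separately. Constraint sets are built by
ordistep-style forward selection with permutation tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import AbundanceTable, SampleMetadata, metadata_frame
from .preprocess import wisconsin_double_standardize


@dataclass
class DistanceMatrix:
    d: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        self.d = d


def bray_curtis(matrix: np.ndarray, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between rows (samples x taxa input)."""
    X = np.asarray(matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("abundances must be non-negative")
    sums = X.sum(axis=1)
    if np.any(sums <= 0):
        bad = np.flatnonzero(sums <= 0).tolist()
        raise ValueError(f"zero-sum sample rows: {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    ids = sample_ids or [f"row{i}" for i in range(X.shape[0])]
    return DistanceMatrix(d, list(ids))


@dataclass
class OrdinationResult:
    total_inertia: float
    constrained_inertia: float
    explained_fraction: float
    adjusted_r2: float
    axes: np.ndarray
    selected_constraints: list[dict] = field(default_factory=list)
    n_permutations: int = 0
    negative_inertia: float = 0.0
    dropped_constraints: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "total_inertia": self.total_inertia,
            "constrained_inertia": self.constrained_inertia,
            "explained_fraction": self.explained_fraction,
            "adjusted_r2": self.adjusted_r2,
            "axes": [float(a) for a in self.axes],
            "selected_constraints": self.selected_constraints,
            "n_permutations": self.n_permutations,
            "negative_inertia": self.negative_inertia,
            "dropped_constraints": self.dropped_constraints,
        }


def _gower_coordinates(d: np.ndarray) -> tuple[np.ndarray, float, float]:
    """PCoA coordinates on positive eigenvalues; returns (Y, pos, neg inertia)."""
    n = d.shape[0]
    d2 = d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J
    G = (G + G.T) / 2
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(np.abs(vals).max(), 1.0) * 1e-10
    pos = vals > tol
    Y = vecs[:, pos] * np.sqrt(vals[pos])
    return Y, float(vals[pos].sum()), float(-vals[vals < -tol].sum())


def _constraint_basis(Z: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Orthonormal basis of the centered constraint space; drops redundant
    (rank-deficient) columns and returns the dropped column indices."""
    Zc = Z - Z.mean(axis=0)
    sd = Zc.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance constraint column")
    Zc = Zc / sd
    Q, R = np.linalg.qr(Zc, mode="reduced")
    diag = np.abs(np.diag(R))
    keep = diag > max(diag.max(), 1.0) * 1e-10
    dropped = []
    if not keep.all():
        # re-orthogonalise the independent columns only
        cols = []
        basis = np.zeros((Zc.shape[0], 0))
        for j in range(Zc.shape[1]):
            resid = Zc[:, j] - basis @ (basis.T @ Zc[:, j])
            nrm = np.linalg.norm(resid)
            if nrm > 1e-8 * max(np.linalg.norm(Zc[:, j]), 1.0):
                basis = np.column_stack([basis, resid / nrm])
                cols.append(j)
            else:
                dropped.append(j)
        warnings.warn(f"dropped {len(dropped)} collinear constraint column(s)")
        return basis, dropped
    return Q, dropped


def dbrda(
    dist: DistanceMatrix,
    constraints: np.ndarray | pd.DataFrame,
    selected_names: list[str] | None = None,
) -> OrdinationResult:
    """Distance-based redundancy analysis of ``dist`` on the constraints."""
    names = None
    if isinstance(constraints, pd.DataFrame):
        names = list(constraints.columns)
        constraints = constraints.values
    Z = np.atleast_2d(np.asarray(constraints, dtype=float))
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != dist.d.shape[0]:
        raise ValueError("constraints and distances have different sample counts")

    Y, total_pos, neg = _gower_coordinates(dist.d)
    Q, dropped_idx = _constraint_basis(Z)
    Yhat = Q @ (Q.T @ Y)
    constrained = float((Yhat ** 2).sum())
    sv = np.linalg.svd(Yhat, compute_uv=False)
    axes = (sv ** 2)[: Q.shape[1]]
    n, q = Z.shape[0], Q.shape[1]
    r2 = constrained / total_pos if total_pos > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - q - 1, 1)
    dropped_names = (
        [names[i] for i in dropped_idx] if names else [str(i) for i in dropped_idx]
    )
    return OrdinationResult(
        total_inertia=total_pos,
        constrained_inertia=constrained,
        explained_fraction=r2,
        adjusted_r2=adj,
        axes=axes,
        selected_constraints=[{"name": nm} for nm in (selected_names or [])],
        negative_inertia=neg,
        dropped_constraints=dropped_names,
    )


def forward_select(
    dist: DistanceMatrix,
    candidates: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 999,
    seed: int = 0,
    collinearity_r2: float = 0.998,
) -> OrdinationResult:
    """Ordistep-style forward selection of constraints with permutation tests.

    At each step the candidate with the largest marginal pseudo-F (given the
    already-selected set) is tested by freely permuting its rows; it is
    added when the permutation p-value is below ``alpha``. Candidates nearly
    collinear with the selected set are skipped.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    if candidates.shape[1] and n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    n = dist.d.shape[0]
    Y, total_pos, _ = _gower_coordinates(dist.d)

    names = list(candidates.columns)
    C = candidates.values.astype(float)
    C = C - C.mean(axis=0)
    sd = C.std(axis=0)
    usable = sd > 0
    C[:, usable] = C[:, usable] / sd[usable]

    selected: list[int] = []
    records: list[dict] = []
    basis = np.zeros((n, 0))
    inertia_sel = 0.0

    def added_inertia(col: np.ndarray) -> tuple[float, float]:
        """(inertia gained by col beyond basis, residual norm fraction)."""
        resid = col - basis @ (basis.T @ col)
        nrm2 = float(resid @ resid)
        tot2 = float(col @ col)
        if nrm2 <= 1e-12 * max(tot2, 1.0):
            return 0.0, 0.0
        qv = resid / np.sqrt(nrm2)
        return float(((qv @ Y) ** 2).sum()), nrm2 / max(tot2, 1e-300)

    while True:
        best_j, best_gain = None, -np.inf
        for j in range(C.shape[1]):
            if j in selected or not usable[j]:
                continue
            gain, resid_frac = added_inertia(C[:, j])
            if resid_frac < (1.0 - collinearity_r2):
                continue  # collinear with selected set
            if gain > best_gain:
                best_j, best_gain = j, gain
        if best_j is None:
            break

        df_resid = n - len(selected) - 2
        if df_resid <= 0:
            break
        resid_inertia = total_pos - inertia_sel - best_gain
        f_obs = best_gain / max(resid_inertia / df_resid, 1e-300)

        # permutation null: freely permute the candidate's rows
        col = C[:, best_j]
        perms = np.column_stack(
            [col[rng.permutation(n)] for _ in range(n_perm)]
        )
        resid_p = perms - basis @ (basis.T @ perms)
        nrm = np.linalg.norm(resid_p, axis=0)
        nrm[nrm < 1e-12] = np.inf
        gains = ((Y.T @ (resid_p / nrm)) ** 2).sum(axis=0)
        f_perm = gains / np.maximum(
            (total_pos - inertia_sel - gains) / df_resid, 1e-300
        )
        pval = (1.0 + float((f_perm >= f_obs).sum())) / (n_perm + 1.0)
        # vegan's ordistep convention: the term enters when p <= alpha
        if pval > alpha:
            break

        resid = col - basis @ (basis.T @ col)
        basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
        selected.append(best_j)
        inertia_sel += best_gain
        records.append(
            {"name": names[best_j], "pseudo_F": float(f_obs), "p": float(pval)}
        )

    if selected:
        result = dbrda(dist, candidates.iloc[:, selected])
    else:
        result = OrdinationResult(
            total_inertia=total_pos,
            constrained_inertia=0.0,
            explained_fraction=0.0,
            adjusted_r2=0.0,
            axes=np.array([]),
        )
    result.selected_constraints = records
    result.n_permutations = n_perm
    return result


def log_standardize_env(env: pd.DataFrame) -> pd.DataFrame:
    """Natural log with a half-minimum-positive offset for zero-containing
    columns (environmental variables are strictly positive concentrations
    or near-positive measurements)."""
    out = {}
    for c in env.columns:
        x = env[c].astype(float)
        positive = x[x > 0]
        offset = 0.0
        if (x <= 0).any():
            offset = (positive.min() / 2.0) if len(positive) else 1.0
            offset += -x.min() if x.min() < 0 else 0.0
        out[c] = np.log(x + offset) if (x + offset > 0).all() else x
    return pd.DataFrame(out, index=env.index)


def keystone_vs_environment(
    bacteria: AbundanceTable,
    keystones16: list[str],
    keystones18: list[str],
    table16: AbundanceTable,
    table18: AbundanceTable,
    meta: list[SampleMetadata],
    env_columns: list[str] | None = None,
    alpha: float = 0.01,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, OrdinationResult]:
    """How much bacterial community variance do keystones vs environment explain?

    Runs forward selection + db-RDA three times on the same Wisconsin-
    standardised bacterial Bray-Curtis matrix, constrained by (1) bacterial
    keystone relative abundances, (2) eukaryotic keystone relative
    abundances, (3) log-standardised environmental variables.
    """
    from .preprocess import relative_abundance

    missing16 = [k for k in keystones16 if k not in table16.taxon_ids]
    missing18 = [k for k in keystones18 if k not in table18.taxon_ids]
    if missing16 or missing18:
        raise ValueError(f"keystones absent from tables: {missing16 + missing18}")

    resp = wisconsin_double_standardize(bacteria.counts.T.astype(float))
    dist = bray_curtis(resp, bacteria.sample_ids)

    def keystone_columns(table: AbundanceTable, ids: list[str]) -> pd.DataFrame:
        rel = relative_abundance(table)
        rows = [table.taxon_ids.index(k) for k in ids]
        return pd.DataFrame(
            rel[rows, :].T, index=table.sample_ids, columns=ids
        ).loc[bacteria.sample_ids]

    mframe = metadata_frame(meta).loc[bacteria.sample_ids]
    env_cols = env_columns or [
        c
        for c in mframe.columns
        if c not in ("floodplain", "stream_type", "deglaciation",
                     "consistent_categorisation")
    ]
    env = log_standardize_env(mframe[env_cols].astype(float).dropna(axis=1))

    report = {}
    for label, cand, sub_seed in (
        ("bacterial_keystones", keystone_columns(table16, keystones16), 1),
        ("eukaryotic_keystones", keystone_columns(table18, keystones18), 2),
        ("environment", env, 3),
    ):
        report[label] = forward_select(
            dist, cand, alpha=alpha, n_perm=n_perm, seed=seed + sub_seed
        )
    return report


@dataclass
class EnrichmentResult:
    family: str
    factor_effects: dict[str, dict[str, float]]  # effect -> {"F":, "p":}
    adjusted_p: dict[str, float]


def family_enrichment(
    family_matrix: pd.DataFrame,
    meta: list[SampleMetadata],
    factors: tuple[str, str] = ("stream_type", "deglaciation"),
) -> list[EnrichmentResult]:
    """Two-way fixed-effects ANOVA per family, BH-adjusted across families.

    ``family_matrix`` is family x sample relative abundances; the two
    factors and their interaction are tested for every family and p-values
    adjusted per effect across families.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multitest import multipletests

    mframe = metadata_frame(meta)
    samples = [s for s in family_matrix.columns if s in mframe.index]
    design = mframe.loc[samples, list(factors)]
    cells = design.groupby(list(factors)).size()
    if len(cells) < 4 or (cells < 2).any():
        warnings.warn("factor cells with < 2 samples; enrichment skipped")
        return []

    fa, fb = factors
    effects = [f"C({fa})", f"C({fb})", f"C({fa}):C({fb})"]
    raw: dict[str, list[float]] = {e: [] for e in effects}
    stats_f: dict[str, list[float]] = {e: [] for e in effects}
    families = list(family_matrix.index)
    for fam in families:
        df = design.copy()
        df["y"] = family_matrix.loc[fam, samples].values
        model = smf.ols(f"y ~ C({fa}) * C({fb})", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sm.stats.anova_lm(model, typ=2)
        for e in effects:
            raw[e].append(float(table.loc[e, "PR(>F)"]))
            stats_f[e].append(float(table.loc[e, "F"]))

    adjusted = {
        e: multipletests(np.nan_to_num(raw[e], nan=1.0), method="fdr_bh")[1]
        for e in effects
    }
    out = []
    for i, fam in enumerate(families):
        out.append(
            EnrichmentResult(
                family=fam,
                factor_effects={
                    e: {"F": stats_f[e][i], "p": raw[e][i]} for e in effects
                },
                adjusted_p={e: float(adjusted[e][i]) for e in effects},
            )
        )
    return out
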