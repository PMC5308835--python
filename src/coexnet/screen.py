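"""Seed-gene correlation screen within one expression dataset.

Every non-seed feature is correlated (Pearson, pairwise-complete
observations) with the seed feature; a feature passes when |r| strictly
exceeds the threshold (default 0.55) and enough complete pairs support it.
Analytic p-values use the t transform t = r * sqrt((n-2)/(1-r^2)) with n-2
degrees of freedom; a seeded permutation p-value is available as a
distribution-free alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SeedLookupError, ValidationError
from .ingest import ExpressionMatrix, FeatureAnnotation

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Parameters of a single-dataset screen.

    seed may be a gene symbol or an explicit feature id. r_threshold is the
    absolute-correlation cut (strict ">"); min_pairs is the minimum number of
    pairwise-complete samples for r to be defined as evidence.
    """

    seed: str
    r_threshold: float = 0.55
    p_method: str = "analytic"  # analytic | permutation | both
    n_permutations: int = 10_000
    min_pairs: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ValidationError("r_threshold must be strictly between 0 and 1")
        if self.min_pairs < 3:
            raise ValidationError("min_pairs must be >= 3")
        if self.p_method not in ("analytic", "permutation", "both"):
            raise ValidationError(f"unknown p_method {self.p_method!r}")
        if self.p_method != "analytic" and self.n_permutations < 99:
            raise ValidationError("n_permutations must be >= 99")


@dataclass
class CorrelationRecord:
    feature_id: str
    gene_symbol: str
    n_pairs: int
    r: float  # NaN when undefined
    p_analytic: float
    p_permutation: float | None
    direction: int  # sign of r: -1, 0, +1 (0 also for undefined r)
    passes: bool


@dataclass
class ScreenResult:
    dataset_id: str
    seed_feature_id: str
    config: ScreenConfig
    records: list[CorrelationRecord]
    passing_ids: list[str] = field(default_factory=list)

    def record_for(self, feature_id: str) -> CorrelationRecord:
        return self._index[feature_id]

    def __post_init__(self) -> None:
        self._index = {rec.feature_id: rec for rec in self.records}

    @property
    def n_passing(self) -> int:
        return len(self.passing_ids)


def resolve_seed(
    expr: ExpressionMatrix, annotation: FeatureAnnotation, seed: str
) -> str:
    """Resolve a seed symbol or feature id to a concrete feature id.

    An explicit feature id wins; otherwise among features annotated to the
    symbol the one with highest variance over non-missing samples is taken
    (tie -> lexicographically smallest id).
    """
    if seed in expr.values.index:
        return seed
    candidates = [
        f for f in annotation.features_for_symbol(seed) if f in expr.values.index
    ]
    if not candidates:
        known = sorted({s for s in annotation.symbols.values() if s})
        target = seed.upper()
        near = [s for s in known if s.startswith(target[:3])][:5]
        raise SeedLookupError(
            f"seed {seed!r} matches no feature id or symbol; nearest symbols: {near}"
        )
    sub = expr.values.loc[candidates].to_numpy()
    with np.errstate(invalid="ignore"):
        variances = np.nanvar(sub, axis=1, ddof=1)
    variances = np.where(np.isfinite(variances), variances, -np.inf)
    best = min(zip(-variances, candidates))  # max variance, then smallest id
    return best[1]


def pearson_r(x, y, min_pairs: int = 3) -> tuple[float, int]:
    """Pearson correlation over pairwise-complete positions.

    Returns (r, n_pairs); r is NaN when fewer than min_pairs complete pairs
    exist or either variable is constant over the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_r requires equal-length 1-D vectors")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < max(min_pairs, 2):
        return float("nan"), n
    xs, ys = x[mask], y[mask]
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan"), n
    r = float((xc @ yc) / denom)
    return min(1.0, max(-1.0, r)), n


def correlation_p_analytic(r: float, n_pairs: int) -> float:
    """Two-sided p for a Pearson r via the Student-t transform (df = n-2)."""
    if n_pairs < 3:
        raise ValueError("analytic p-value requires n_pairs >= 3")
    if not np.isfinite(r):
        return float("nan")
    if abs(r) >= 1.0:
        return float(np.nextafter(0.0, 1.0))
    t = r * np.sqrt((n_pairs - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n_pairs - 2)
    return float(min(1.0, max(p, np.nextafter(0.0, 1.0))))


def correlation_p_permutation(
    x, y, n_permutations: int = 10_000, rng_seed: int = 0, min_pairs: int = 3
) -> float:
    """Permutation p-value for |r| with the add-one correction.

    y is permuted over the complete pairs B times with a seeded generator;
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + B). Deterministic given rng_seed.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[mask], y[mask]
    r_obs, n = pearson_r(xs, ys, min_pairs=min_pairs)
    if not np.isfinite(r_obs):
        return float("nan")
    rng = np.random.default_rng(rng_seed)
    xc = xs - xs.mean()
    xc /= np.sqrt(xc @ xc)
    yc = ys - ys.mean()
    yc /= np.sqrt(yc @ yc)
    perms = rng.permuted(
        np.broadcast_to(yc, (n_permutations, n)).copy(), axis=1
    )
    r_perm = perms @ xc
    hits = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-15))
    return (1 + hits) / (1 + n_permutations)


def _bulk_pearson(seed_vec: np.ndarray, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson r of every row of ``mat`` against seed_vec.

    Vectorized over features: per-feature masked sums give the same result
    as pearson_r on each row. Returns (r, n_pairs) arrays; r is NaN where
    undefined (zero variance over the complete pairs).
    """
    s_fin = np.isfinite(seed_vec)
    m_fin = np.isfinite(mat)
    w = m_fin & s_fin  # features x samples joint-complete mask
    n = w.sum(axis=1).astype(float)
    s = np.where(s_fin, seed_vec, 0.0)
    xm = np.where(m_fin, mat, 0.0)
    sum_x = (xm * w).sum(axis=1)
    sum_s = w @ s
    sum_xx = (xm * xm * w).sum(axis=1)
    sum_ss = w @ (s * s)
    sum_xs = (xm * w) @ s
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sum_xs - sum_x * sum_s / n
        var_x = sum_xx - sum_x * sum_x / n
        var_s = sum_ss - sum_s * sum_s / n
        denom = np.sqrt(var_x * var_s)
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    return r, n.astype(int)


def run_screen(
    expr: ExpressionMatrix,
    annotation: FeatureAnnotation,
    config: ScreenConfig,
) -> ScreenResult:
    """Correlate every non-seed feature to the seed and apply the threshold.

    A record passes iff |r| > r_threshold (strict) and n_pairs >= min_pairs.
    passing_ids are ordered by descending |r|, ties lexicographic.
    """
    seed_id = resolve_seed(expr, annotation, config.seed)
    feature_ids = np.array(expr.feature_ids)
    other = feature_ids != seed_id
    mat = expr.values.to_numpy()[other]
    seed_vec = expr.values.loc[seed_id].to_numpy()

    r_all, n_all = _bulk_pearson(seed_vec, mat)
    ids = feature_ids[other]

    df = n_all - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r_all * np.sqrt(np.maximum(df, 1) / np.maximum(1.0 - r_all * r_all, 1e-300))
    p_analytic = np.full(len(ids), np.nan)
    ok = np.isfinite(r_all) & (df >= 1)
    p_analytic[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=df[ok])
    p_analytic = np.clip(p_analytic, np.nextafter(0.0, 1.0), 1.0)

    defined = np.isfinite(r_all)
    passes = defined & (np.abs(r_all) > config.r_threshold) & (n_all >= config.min_pairs)

    do_perm = config.p_method in ("permutation", "both")
    records: list[CorrelationRecord] = []
    for i, fid in enumerate(ids):
        r = float(r_all[i])
        p_perm = None
        if do_perm and np.isfinite(r):
            p_perm = correlation_p_permutation(
                seed_vec,
                mat[i],
                n_permutations=config.n_permutations,
                rng_seed=config.rng_seed + i,
                min_pairs=config.min_pairs,
            )
        records.append(
            CorrelationRecord(
                feature_id=str(fid),
                gene_symbol=annotation.symbol_of(str(fid)),
                n_pairs=int(n_all[i]),
                r=r,
                p_analytic=float(p_analytic[i]) if np.isfinite(r) else float("nan"),
                p_permutation=p_perm,
                direction=int(np.sign(r)) if np.isfinite(r) else 0,
                passes=bool(passes[i]),
            )
        )
    passing = [rec for rec in records if rec.passes]
    passing.sort(key=lambda rec: (-abs(rec.r), rec.feature_id))
    result = ScreenResult(
        dataset_id=expr.dataset_id,
        seed_feature_id=seed_id,
        config=config,
        records=records,
        passing_ids=[rec.feature_id for rec in passing],
    )
    logger.info(
        "screen %s: seed=%s, %d features, %d passing at |r|>%g",
        expr.dataset_id, seed_id, len(records), len(passing), config.r_threshold,
    )
    return result


_SCREEN_COLUMNS = [
    "feature_id", "gene_symbol", "n_pairs", "r",
    "p_analytic", "p_permutation", "passes",
]


def write_screen_tsv(result: ScreenResult, path) -> None:
    """Serialize a ScreenResult as TSV (one row per record, screen order)."""
    def fmt(v):
        if v is None:
            return "NA"
        if isinstance(v, float):
            return "NA" if not np.isfinite(v) else repr(v)
        return str(v)

    with open(str(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_SCREEN_COLUMNS) + "\n")
        for rec in result.records:
            fh.write(
                "\t".join(
                    fmt(v)
                    for v in (
                        rec.feature_id, rec.gene_symbol, rec.n_pairs, rec.r,
                        rec.p_analytic, rec.p_permutation, int(rec.passes),
                    )
                )
                + "\n"
            )


def read_screen_tsv(path, dataset_id: str, config: ScreenConfig) -> ScreenResult:
    """Load a screen table written by write_screen_tsv."""
    df = pd.read_csv(str(path), sep="\t", dtype={"feature_id": str, "gene_symbol": str},
                     na_values=["NA"], keep_default_na=True)
    records = []
    for row in df.itertuples(index=False):
        r = float(row.r) if pd.notna(row.r) else float("nan")
        records.append(
            CorrelationRecord(
                feature_id=str(row.feature_id),
                gene_symbol="" if pd.isna(row.gene_symbol) else str(row.gene_symbol),
                n_pairs=int(row.n_pairs),
                r=r,
                p_analytic=float(row.p_analytic) if pd.notna(row.p_analytic) else float("nan"),
                p_permutation=float(row.p_permutation) if pd.notna(row.p_permutation) else None,
                direction=int(np.sign(r)) if np.isfinite(r) else 0,
                passes=bool(int(row.passes)),
            )
        )
    passing = sorted(
        (rec for rec in records if rec.passes),
        key=lambda rec: (-abs(rec.r), rec.feature_id),
    )
    return ScreenResult(
        dataset_id=dataset_id,
        seed_feature_id=config.seed,
        config=config,
        records=records,
        passing_ids=[rec.feature_id for rec in passing],
    )
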