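"""Cross-dataset candidate intersection and concordance.

Two independent screens against the same seed gene are intersected: a
candidate must pass the absolute-correlation threshold in BOTH datasets.
Matching is at feature (probeset) level when both datasets share a platform,
or at gene-symbol level otherwise, where a symbol passes in a dataset if any
of its probes passes and the max-|r| probe represents it. Direction
concordance (agreement of correlation sign across datasets) is reported per
candidate and as a set-level fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .ingest import FeatureAnnotation
from .screen import CorrelationRecord, ScreenResult


@dataclass
class CandidateRecord:
    match_key: str  # feature id or gene symbol depending on matching level
    symbol: str
    feature_id_1: str
    feature_id_2: str
    r1: float
    p1: float
    r2: float
    p2: float
    concordant: bool
    rank_score: float = float("nan")


@dataclass
class CandidateSet:
    matching_level: str  # "feature" | "symbol"
    seed: str
    records: list[CandidateRecord]
    n_passing_1: int
    n_passing_2: int

    @property
    def n_intersection(self) -> int:
        return len(self.records)

    @property
    def n_union(self) -> int:
        return self.n_passing_1 + self.n_passing_2 - self.n_intersection

    @property
    def concordance_defined(self) -> bool:
        return bool(self.records)

    @property
    def concordance_fraction(self) -> float:
        """Fraction of candidates whose correlation signs agree; 1.0 by
        convention on an empty set (see concordance_defined)."""
        if not self.records:
            return 1.0
        return sum(rec.concordant for rec in self.records) / len(self.records)

    def counts(self) -> dict[str, float]:
        return {
            "passing_1": self.n_passing_1,
            "passing_2": self.n_passing_2,
            "intersection": self.n_intersection,
            "union": self.n_union,
            "concordance_fraction": self.concordance_fraction,
        }


def _passing_by_symbol(
    screen: ScreenResult, annotation: FeatureAnnotation
) -> dict[str, CorrelationRecord]:
    """Map symbol -> representative passing record (max |r|, tie by id)."""
    best: dict[str, CorrelationRecord] = {}
    for fid in screen.passing_ids:
        rec = screen.record_for(fid)
        sym = rec.gene_symbol or annotation.symbol_of(fid)
        if not sym:
            continue
        cur = best.get(sym)
        if cur is None or (-abs(rec.r), rec.feature_id) < (-abs(cur.r), cur.feature_id):
            best[sym] = rec
    return best


def intersect_screens(
    a: ScreenResult,
    b: ScreenResult,
    annotation_a: FeatureAnnotation,
    annotation_b: FeatureAnnotation,
    level: str = "feature",
) -> CandidateSet:
    """Candidates passing in both screens, with concordance flags.

    level="feature" matches probeset/feature ids directly (requires a shared
    platform); level="symbol" matches uppercased gene symbols, each symbol
    represented by its max-|r| passing probe per dataset.
    """
    if level not in ("feature", "symbol"):
        raise ValidationError(f"unknown matching level {level!r}")
    seed_a = a.config.seed.upper()
    seed_b = b.config.seed.upper()
    if seed_a != seed_b:
        raise ValidationError(
            f"screens target different seeds: {a.config.seed!r} vs {b.config.seed!r}"
        )

    if level == "feature":
        pass_a = {fid: a.record_for(fid) for fid in a.passing_ids}
        pass_b = {fid: b.record_for(fid) for fid in b.passing_ids}
    else:
        pass_a = _passing_by_symbol(a, annotation_a)
        pass_b = _passing_by_symbol(b, annotation_b)

    records = []
    for key in sorted(set(pass_a) & set(pass_b)):
        ra, rb = pass_a[key], pass_b[key]
        records.append(
            CandidateRecord(
                match_key=key,
                symbol=ra.gene_symbol or rb.gene_symbol or (key if level == "symbol" else ""),
                feature_id_1=ra.feature_id,
                feature_id_2=rb.feature_id,
                r1=ra.r,
                p1=ra.p_analytic,
                r2=rb.r,
                p2=rb.p_analytic,
                concordant=bool(ra.r * rb.r > 0),
            )
        )
    return CandidateSet(
        matching_level=level,
        seed=seed_a,
        records=records,
        n_passing_1=len(pass_a),
        n_passing_2=len(pass_b),
    )


def concordance_report(cs: CandidateSet) -> tuple[float, list[str]]:
    """Concordance fraction and the sorted discordant match keys.

    Raises on an empty candidate set rather than silently reporting 1.0.
    """
    if not cs.records:
        raise ValidationError("concordance undefined on an empty candidate set")
    discordant = sorted(rec.match_key for rec in cs.records if not rec.concordant)
    return cs.concordance_fraction, discordant


def rank_candidates(cs: CandidateSet, method: str = "min_abs_r") -> list[CandidateRecord]:
    """Order candidates by a per-dataset |r| summary, descending.

    method="min_abs_r" ranks by the weaker of the two correlations (a
    conservative cross-dataset magnitude); "mean_abs_r" by their mean. Ties
    break lexicographically by match key. rank_score is set on the records.
    """
    if method not in ("min_abs_r", "mean_abs_r"):
        raise ValidationError(f"unknown ranking method {method!r}")
    for rec in cs.records:
        pair = (abs(rec.r1), abs(rec.r2))
        rec.rank_score = min(pair) if method == "min_abs_r" else sum(pair) / 2.0
    return sorted(cs.records, key=lambda rec: (-rec.rank_score, rec.match_key))


_TABLE_COLUMNS = [
    "match_key", "symbol", "r_ds1", "p_ds1", "r_ds2", "p_ds2",
    "concordant", "rank_score",
]


def write_candidate_table(cs: CandidateSet, path, method: str = "min_abs_r") -> None:
    """Write the candidate table as TSV in deterministic rank order."""
    ordered = rank_candidates(cs, method) if cs.records else []

    def fmt(v) -> str:
        if isinstance(v, float):
            return "NA" if not np.isfinite(v) else repr(v)
        return str(v)

    with open(str(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for rec in ordered:
            fh.write(
                "\t".join(
                    fmt(v)
                    for v in (
                        rec.match_key, rec.symbol, rec.r1, rec.p1,
                        rec.r2, rec.p2, int(rec.concordant), rec.rank_score,
                    )
                )
                + "\n"
            )


def read_candidate_table(path) -> list[CandidateRecord]:
    """Load candidate records written by write_candidate_table."""
    records = []
    with open(str(path), encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header != _TABLE_COLUMNS:
            raise ValidationError(f"{path}: unexpected candidate-table header")
        for line in fh:
            toks = line.rstrip("\r\n").split("\t")
            if len(toks) != len(_TABLE_COLUMNS):
                continue
            def num(tok: str) -> float:
                return float("nan") if tok == "NA" else float(tok)
            records.append(
                CandidateRecord(
                    match_key=toks[0],
                    symbol=toks[1],
                    feature_id_1=toks[0],
                    feature_id_2=toks[0],
                    r1=num(toks[2]),
                    p1=num(toks[3]),
                    r2=num(toks[4]),
                    p2=num(toks[5]),
                    concordant=bool(int(toks[6])),
                    rank_score=num(toks[7]),
                )
            )
    return records
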