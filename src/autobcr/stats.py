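"""Cohort-level association statistics and sequence-homology summaries.

Covers the Fisher exact test for the isotype x signaling association, the
Wilcoxon tests used for group comparisons of signaling strength, percent
identity of a rearranged IGHV sequence to its germline allele (a somatic
hypermutation readout), and a cohort summary that assembles all of these
from a per-case annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact",
    "rank_test",
    "ighv_homology",
    "cohort_summary",
    "COHORT_COLUMNS",
]

#: Required columns of a cohort annotation table.
COHORT_COLUMNS = ("case_id", "isotype", "signaling")

EXACT_RANK_N = 25  # exact null enumeration up to this sample size

_GAP_CHARS = frozenset("-.nN")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Four counts with labels; row = first factor level, column = second."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2):
            raise ValueError(f"need a 2x2 table, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("table total must be > 0")

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


def fisher_exact(table, sided: str = "two-sided") -> float:
    """Exact hypergeometric P for a 2x2 table.

    The two-sided P sums the probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    ``table`` may be a :class:`ContingencyTable2x2` or any 2x2 array-like.
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.values
    else:
        arr = np.asarray(table, dtype=int)
        if arr.shape != (2, 2):
            raise ValueError(f"need a 2x2 table, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("table total must be > 0")
    if sided not in ("two-sided", "less", "greater"):
        raise ValueError(f"sided must be two-sided/less/greater, got {sided!r}")
    return float(sps.fisher_exact(arr, alternative=sided).pvalue)


def rank_test(
    group_a, group_b, variant: str = "signed_rank", sided: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank test: paired signed-rank or independent rank-sum.

    The null distribution is enumerated exactly for n <= 25 (when free of
    ties/zeros); larger samples use the normal approximation with continuity
    correction.  All paired differences zero returns (0.0, 1.0) by
    convention.  Returns ``(statistic, p_value)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if sided not in ("two-sided", "less", "greater"):
        raise ValueError(f"sided must be two-sided/less/greater, got {sided!r}")
    if variant == "signed_rank":
        if len(a) != len(b):
            raise ValueError(
                f"signed-rank test needs equal-length paired samples, got ({len(a)}, {len(b)})"
            )
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        nz = d[d != 0]
        exact_ok = len(nz) <= EXACT_RANK_N and len(np.unique(np.abs(nz))) == len(nz)
        res = sps.wilcoxon(
            a, b,
            alternative=sided,
            method="exact" if exact_ok else "approx",
            correction=not exact_ok,
        )
    elif variant == "rank_sum":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("rank-sum test needs two non-empty samples")
        pooled = np.concatenate([a, b])
        exact_ok = (
            max(len(a), len(b)) <= EXACT_RANK_N
            and len(np.unique(pooled)) == len(pooled)
        )
        res = sps.mannwhitneyu(
            a, b,
            alternative=sided,
            method="exact" if exact_ok else "asymptotic",
            use_continuity=True,
        )
    else:
        raise ValueError(f"variant must be signed_rank or rank_sum, got {variant!r}")
    return float(res.statistic), float(res.pvalue)


def ighv_homology(sequence: str, germline_reference: str) -> float:
    """Percent nucleotide identity to the germline allele, on pre-aligned
    (e.g. IMGT-gapped) sequences of equal length.

    Positions where either sequence carries a gap (``-``/``.``) or ``N`` are
    excluded from the comparison; identity is 100 x matches / compared
    positions, reported to 0.1%.
    """
    if len(sequence) != len(germline_reference):
        raise ValueError(
            f"sequences must be pre-aligned to equal length, got "
            f"({len(sequence)}, {len(germline_reference)})"
        )
    matches = compared = 0
    for x, y in zip(sequence, germline_reference):
        if x in _GAP_CHARS or y in _GAP_CHARS:
            continue
        compared += 1
        if x.upper() == y.upper():
            matches += 1
    if compared == 0:
        raise ValueError("no comparable (ungapped, non-N) positions")
    return round(100.0 * matches / compared, 1)


def _signaling_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("signaling", "yes", "true", "1")
    return bool(v)


def cohort_summary(table: pd.DataFrame) -> dict:
    """Counts, association P values and homology summary for a cohort.

    ``table`` needs columns case_id, isotype and signaling, and optionally
    coo (ABC/GCB/non-GCB/unclassified), cluster and homology_percent.
    Signaling may be boolean or the strings signaling/non_signaling.
    The isotype association tests IgM vs non-IgM; the cell-of-origin
    association tests ABC/non-GCB vs GCB among cases with a known call.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    if len(table) == 0:
        raise ValueError("cohort table must contain at least one case")
    if table["case_id"].duplicated().any():
        dupes = table.loc[table["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case_id(s): {dupes}")

    sig = table["signaling"].map(_signaling_bool).to_numpy()
    isotype = table["isotype"].astype(str).str.upper()
    is_igm = isotype.str.startswith("IGM").to_numpy()

    out: dict = {
        "n_cases": int(len(table)),
        "n_signaling": int(sig.sum()),
        "signaling_by_isotype": {
            iso: int(sig[(isotype == iso).to_numpy()].sum()) for iso in sorted(isotype.unique())
        },
    }
    iso_table = [
        [int((is_igm & sig).sum()), int((is_igm & ~sig).sum())],
        [int((~is_igm & sig).sum()), int((~is_igm & ~sig).sum())],
    ]
    out["isotype_table"] = iso_table
    out["fisher_isotype_p"] = (
        fisher_exact(iso_table) if np.asarray(iso_table).sum() > 0 else None
    )

    if "coo" in table.columns:
        coo = table["coo"].astype(str).str.upper().str.replace("-", "_")
        known = coo.isin(["ABC", "NON_GCB", "GCB"]).to_numpy()
        is_abc = coo.isin(["ABC", "NON_GCB"]).to_numpy()
        coo_table = [
            [int((known & is_abc & sig).sum()), int((known & is_abc & ~sig).sum())],
            [int((known & ~is_abc & sig).sum()), int((known & ~is_abc & ~sig).sum())],
        ]
        out["coo_table"] = coo_table
        out["signaling_by_coo"] = {
            c: int(sig[(coo == c).to_numpy()].sum()) for c in sorted(coo.unique())
        }
        out["fisher_coo_p"] = (
            fisher_exact(coo_table) if np.asarray(coo_table).sum() > 0 else None
        )

    if "homology_percent" in table.columns:
        h = table["homology_percent"].dropna().to_numpy(dtype=float)
        if np.any((h < 0) | (h > 100)):
            raise ValueError("homology_percent values must lie in [0, 100]")
        if len(h):
            out["homology"] = {
                "median": float(np.median(h)),
                "min": float(h.min()),
                "max": float(h.max()),
                "n": int(len(h)),
            }
    return out
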