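"""Cross-comparison summaries: call-set overlaps, DE x DEU cross-tabs, tests.

These operate on finished call sets (or their TSV exports) and reproduce
the usual downstream bookkeeping: how many called exons/genes are shared
between comparisons, how differential exon usage distributes over genes
that are themselves up-/down-/un-changed as a whole, whether an observed
overlap between two exon sets is larger than chance (hypergeometric
upper tail), and whether the DEU fraction differs across subtypes
(Pearson chi-square).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapSummary",
    "overlap_summary",
    "share_pct",
    "de_crosstab",
    "hypergeometric_overlap",
    "write_reports",
]


def share_pct(part: int, whole: int, digits: int = 1) -> float:
    """Percentage part/whole, rounded half-up to ``digits`` decimals; NaN if whole=0."""
    if whole == 0:
        return float("nan")
    raw = 100.0 * part / whole
    factor = 10**digits
    return math.floor(raw * factor + 0.5) / factor


@dataclass(frozen=True)
class OverlapSummary:
    """Set algebra over 2-3 call sets for one label (+1 or -1).

    ``singles`` maps comparison name -> count; ``pairs`` maps frozensets
    of two names; ``triple`` is the full intersection (0 for two sets).
    The inclusion-exclusion identity union = sum(singles) - sum(pairs)
    + triple holds by construction and is re-checked on creation.
    """

    label: int
    level: str  # "exon" | "gene"
    singles: dict[str, int]
    pairs: dict[frozenset, int]
    triple: int
    union: int
    triple_share_pct: float

    def __post_init__(self) -> None:
        incl_excl = sum(self.singles.values()) - sum(self.pairs.values()) + (
            self.triple if len(self.singles) == 3 else 0
        )
        if incl_excl != self.union:
            raise ValueError("inclusion-exclusion identity violated")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "level": self.level,
            "singles": dict(self.singles),
            "pairs": {"&".join(sorted(k)): v for k, v in self.pairs.items()},
            "triple": self.triple,
            "union": self.union,
            "triple_share_pct": self.triple_share_pct,
        }


def _called_sets(callsets: Mapping[str, pd.DataFrame], label: int, level: str):
    out = {}
    for name, table in callsets.items():
        called = table[table["final_call"] == label]
        if level == "exon":
            out[name] = set(called.index)
        else:
            out[name] = set(called["gene_id"])
    return out


def overlap_summary(
    callsets: Mapping[str, pd.DataFrame], label: int, level: str = "exon"
) -> OverlapSummary:
    """Exact overlap counts of called exon (or gene) sets across comparisons.

    ``callsets`` maps comparison name -> exon call table (indexed by
    exon_id, with final_call and gene_id columns) on a shared exon
    universe.  The triple share is the full-intersection count as a
    percentage of the union (NA when the union is empty).
    """
    if not (2 <= len(callsets) <= 3):
        raise ValueError("overlap summary takes 2 or 3 call sets")
    universes = [set(t.index) for t in callsets.values()]
    if not set.intersection(*universes):
        raise ValueError("call sets share no exons; universes are disjoint")
    sets = _called_sets(callsets, label, level)
    names = list(sets)
    singles = {n: len(sets[n]) for n in names}
    pairs = {
        frozenset((a, b)): len(sets[a] & sets[b]) for a, b in itertools.combinations(names, 2)
    }
    triple = len(set.intersection(*sets.values())) if len(names) == 3 else 0
    union = len(set.union(*sets.values()))
    return OverlapSummary(
        label=label,
        level=level,
        singles=singles,
        pairs=pairs,
        triple=triple,
        union=union,
        triple_share_pct=share_pct(triple, union) if union else float("nan"),
    )


def de_crosstab(
    callsets: Mapping[str, pd.DataFrame],
    gene_tables: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Cross-tabulate DEU genes against whole-gene expression direction.

    For each comparison (subtype vs reference) and each DE category
    (up / down / similar, from the gene direction call), counts genes
    with +1-called exons, with -1-called exons, total genes with any
    called exon (DEU), unspliced genes, and the total.  For each DE
    category a Pearson chi-square tests whether the DEU/unspliced split
    differs across subtypes; when any expected count falls below 1 the
    Fisher exact test (2 groups) or an exact warning fallback applies.
    """
    if len(callsets) < 2:
        raise ValueError("chi-square across subtypes needs at least 2 comparisons")
    if set(callsets) != set(gene_tables):
        raise ValueError("callsets and gene_tables must cover the same comparisons")
    rows = []
    for name, table in callsets.items():
        gdir = gene_tables[name]["direction"]
        plus_genes = set(table.loc[table["final_call"] == 1, "gene_id"])
        minus_genes = set(table.loc[table["final_call"] == -1, "gene_id"])
        deu_genes = plus_genes | minus_genes
        for cat in ("up", "down", "similar"):
            genes_cat = set(gdir.index[gdir == cat])
            n_deu = len(genes_cat & deu_genes)
            rows.append(
                {
                    "comparison": name,
                    "de_category": cat,
                    "genes_plus_exons": len(genes_cat & plus_genes),
                    "genes_minus_exons": len(genes_cat & minus_genes),
                    "genes_deu": n_deu,
                    "genes_unspliced": len(genes_cat) - n_deu,
                    "genes_total": len(genes_cat),
                }
            )
    crosstab = pd.DataFrame(rows).set_index(["comparison", "de_category"])
    tests = {}
    for cat in ("up", "down", "similar"):
        sub = crosstab.xs(cat, level="de_category")[["genes_deu", "genes_unspliced"]]
        tests[cat] = chi_square_deu(sub.to_numpy())
    return crosstab, tests


def chi_square_deu(table: np.ndarray) -> dict[str, float]:
    """Pearson chi-square (no continuity correction) on a groups x 2 table.

    Falls back to Fisher's exact test when an expected count is below 1
    and the table is 2x2; otherwise the chi-square is still reported with
    a low-expected-count warning flag.
    """
    table = np.asarray(table, dtype=float)
    if table.shape[0] < 2:
        raise ValueError("need at least 2 groups")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # a zero margin leaves the statistic undefined
        return {"chi2": float("nan"), "p": float("nan"), "dof": 0, "low_expected": True}
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    low = bool((expected < 1).any())
    out = {"chi2": float(chi2), "p": float(p), "dof": int(dof), "low_expected": low}
    if low and table.shape == (2, 2):
        out["fisher_p"] = float(stats.fisher_exact(table.astype(int))[1])
    return out


def hypergeometric_overlap(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """Expected overlap and upper-tail p of drawing n from N with K marked.

    Returns ``(expected, p)`` with expected = K*n/N and
    p = P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space
    by scipy so that astronomically small tails stay representable.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    expected = K * n / N
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return expected, p


def write_reports(
    summaries: Sequence[OverlapSummary],
    crosstab: pd.DataFrame | None,
    tests: Mapping[str, Mapping[str, float]] | None,
    prefix: str,
) -> list[str]:
    """Emit the overlap JSON and the crosstab TSV; deterministic output."""
    paths = []
    overlap_path = f"{prefix}.overlap.json"
    payload = {"summaries": [s.to_dict() for s in summaries]}
    if tests is not None:
        payload["chi_square"] = {k: dict(v) for k, v in tests.items()}
    with open(overlap_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
    paths.append(overlap_path)
    if crosstab is not None:
        ct_path = f"{prefix}.crosstab.tsv"
        crosstab.to_csv(ct_path, sep="\t")
        paths.append(ct_path)
    return paths
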