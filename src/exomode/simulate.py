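"""Synthetic exon-expression cohorts with planted class structure and DEU events.

The generator emulates the statistical structure the caller assumes in
real exon-level RNA-seq matrices:

* per-gene log-normal expression baselines with per-exon offsets;
* class-specific overall gene fold changes (a fraction of genes up- or
  down-regulated as a whole — this moves *all* exons of the gene and
  must not trigger exon-level calls);
* planted minority-exon events (exon skipping, alternative first/last
  exon, intronic start) that shift a small subset of a gene's exons by
  a fixed log2 fold change in one class — the ground truth the caller
  is supposed to recover;
* zero-inflated dropouts and a fraction of entirely silent exons, to
  exercise the unexpressed-exon filter and the near-zero-mode exclusion;
* bimodal two-component marker distributions (ESR1-like expression,
  ERBB2-like focal copy number) consistent with each sample's class.

Values are produced on a raw RPKM-like scale:
``value = 2 ** (baseline + exon offset + class gene effect + event shift
+ Gaussian noise)``, zeroed by dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import DEUCallSet
from .classify import CLASS_ER_NEG, CLASS_ER_POS, CLASS_HER2, CLASS_NBS
from .io import ExonExpressionMatrix, ExonRecord

__all__ = ["DEUEvent", "SyntheticSpec", "SyntheticDataset", "generate", "plant_events", "evaluate_calls"]

EVENT_KINDS = ("skip", "alt_first", "alt_last", "intronic_start")


@dataclass(frozen=True)
class DEUEvent:
    """One planted minority-exon event.

    ``delta_fc`` (log2 units) is added to the affected exons in the
    affected class only; its sign is the expected final exon label when
    the affected class is compared (as class A) against any other class.
    """

    gene_index: int
    exon_indices: tuple[int, ...]
    kind: str
    delta_fc: float
    affected_class: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.exon_indices:
            raise ValueError("event must affect at least one exon")
        if self.delta_fc == 0:
            raise ValueError("delta_fc must be nonzero")


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort layout and effect sizes for one synthetic dataset.

    Defaults describe a desk-scale two-group study: 100 genes of 12
    exons, 40 samples in each of two classes, log-normal baselines
    (log2 mean 3, sd 1), 10% of genes with whole-gene class effects
    (log2FC sd 1.5), Gaussian log-scale noise sd 0.5, 5% dropout and
    2% silent exons.
    """

    n_genes: int = 100
    exons_per_gene: int | tuple[int, int] = 12
    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: {CLASS_ER_NEG: 40, CLASS_ER_POS: 40}
    )
    baseline_mean: float = 3.0
    baseline_sd: float = 1.0
    exon_offset_sd: float = 0.5
    de_fraction: float = 0.1
    de_effect_sd: float = 1.5
    noise_sd: float = 0.5
    noise_df: float | None = None  # Student-t degrees of freedom; None = Gaussian
    dropout_rate: float = 0.05
    silent_exon_rate: float = 0.02
    events: tuple[DEUEvent, ...] = ()
    marker_low_mu: float = 2.0
    marker_high_mu: float = 8.0
    marker_cn_low_mu: float = 0.0
    marker_cn_high_mu: float = 3.0
    marker_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.de_fraction, self.dropout_rate, self.silent_exon_rate):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if len(self.class_sizes) < 2:
            raise ValueError("need at least two classes")

    def exon_counts(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.exons_per_gene, int):
            return np.full(self.n_genes, self.exons_per_gene)
        lo, hi = self.exons_per_gene
        return rng.integers(lo, hi + 1, size=self.n_genes)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated matrix plus every piece of ground truth."""

    matrix: ExonExpressionMatrix  # raw RPKM-like scale
    classes: pd.DataFrame  # sample_id -> class
    markers: pd.DataFrame  # sample_id -> esr1_expr, erbb2_focal_cn
    spec: SyntheticSpec
    gene_effects: pd.DataFrame  # gene x class whole-gene log2 effects

    def truth_labels(self, class_a: str, class_b: str) -> pd.Series:
        """Expected exon label (+1/-1/0) for the ordered comparison A - B."""
        labels = pd.Series(0, index=self.matrix.values.index, name="truth", dtype=int)
        gene_ids = self.matrix.gene_ids
        for ev in self.spec.events:
            sign = int(np.sign(ev.delta_fc))
            if ev.affected_class == class_a:
                lab = sign
            elif ev.affected_class == class_b:
                lab = -sign
            else:
                continue
            gid = f"G{ev.gene_index:04d}"
            gene_exons = labels.index[gene_ids == gid]
            for k in ev.exon_indices:
                labels.loc[gene_exons[k]] = lab
        return labels

    def truth_gene_directions(
        self, class_a: str, class_b: str, threshold: float = 1.0
    ) -> pd.Series:
        """Expected whole-gene direction of the ordered comparison A - B."""
        eff = self.gene_effects[class_a] - self.gene_effects[class_b]
        out = pd.Series("similar", index=self.gene_effects.index, name="direction")
        out[eff > threshold] = "up"
        out[eff < -threshold] = "down"
        return out


def plant_events(
    spec: SyntheticSpec,
    n_events: int,
    delta_fc: float,
    affected_class: str,
    max_exons: int = 3,
    rng: np.random.Generator | None = None,
    alternate_sign: bool = True,
) -> SyntheticSpec:
    """Place ``n_events`` random minority-exon events on distinct genes.

    Each event touches at most ``max_exons`` exons and never half or more
    of its gene's exons (the labeling model assumes affected exons are a
    minority).  With ``alternate_sign`` the events alternate between
    ``+delta_fc`` and ``-delta_fc``.
    """
    rng = rng or np.random.default_rng(spec.seed + 7)
    counts = spec.exon_counts(np.random.default_rng(spec.seed))
    if n_events > spec.n_genes:
        raise ValueError("more events than genes")
    genes = rng.choice(spec.n_genes, size=n_events, replace=False)
    events = []
    for i, g in enumerate(sorted(int(x) for x in genes)):
        n_ex = int(counts[g])
        limit = min(max_exons, (n_ex - 1) // 2)
        if limit < 1:
            raise ValueError(f"gene {g} has too few exons ({n_ex}) to host an event")
        k = int(rng.integers(1, limit + 1))
        kind = EVENT_KINDS[i % len(EVENT_KINDS)]
        if kind == "alt_first" or kind == "intronic_start":
            idx = tuple(range(k))
        elif kind == "alt_last":
            idx = tuple(range(n_ex - k, n_ex))
        else:  # skip: internal exons
            start = int(rng.integers(1, n_ex - k))
            idx = tuple(range(start, start + k))
        sign = -1.0 if (alternate_sign and i % 2) else 1.0
        events.append(
            DEUEvent(
                gene_index=g,
                exon_indices=idx,
                kind=kind,
                delta_fc=sign * delta_fc,
                affected_class=affected_class,
            )
        )
    return replace(spec, events=spec.events + tuple(events))


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset from the spec; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    counts = spec.exon_counts(rng)
    class_names = list(spec.class_sizes)

    for ev in spec.events:
        if ev.gene_index >= spec.n_genes:
            raise ValueError(f"event on gene {ev.gene_index} beyond n_genes")
        if ev.affected_class not in spec.class_sizes:
            raise ValueError(f"event class {ev.affected_class!r} not in class_sizes")
        n_ex = int(counts[ev.gene_index])
        if max(ev.exon_indices) >= n_ex:
            raise ValueError(f"event exon index beyond gene {ev.gene_index} ({n_ex} exons)")
        if len(ev.exon_indices) * 2 >= n_ex:
            raise ValueError(
                f"event on gene {ev.gene_index} affects {len(ev.exon_indices)} of "
                f"{n_ex} exons; affected exons must be a minority (< half)"
            )

    # genome layout: one pseudo-chromosome, consecutive non-overlapping exons
    exons: list[ExonRecord] = []
    gene_of_exon: list[str] = []
    pos = 1000
    for g in range(spec.n_genes):
        gid = f"G{g:04d}"
        for _ in range(int(counts[g])):
            start0, end = pos, pos + 150
            exons.append(
                ExonRecord(
                    exon_id=f"chrS:{start0 + 1}-{end}",
                    chrom="chrS",
                    start=start0,
                    end=end,
                    gene_id=gid,
                )
            )
            gene_of_exon.append(gid)
            pos = end + 350
        pos += 5000
    n_exons = len(exons)

    samples: list[str] = []
    sample_class: list[str] = []
    for cname in class_names:
        for i in range(spec.class_sizes[cname]):
            samples.append(f"{cname}_{i:03d}")
            sample_class.append(cname)
    n_samples = len(samples)
    class_idx = {c: np.array([i for i, sc in enumerate(sample_class) if sc == c]) for c in class_names}

    gene_base = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    exon_offset = rng.normal(0.0, spec.exon_offset_sd, size=n_exons)

    # whole-gene class effects relative to the first class (kept at 0)
    effects = np.zeros((spec.n_genes, len(class_names)))
    n_de = int(round(spec.de_fraction * spec.n_genes))
    for j, cname in enumerate(class_names[1:], start=1):
        de_genes = rng.choice(spec.n_genes, size=n_de, replace=False)
        effects[de_genes, j] = rng.normal(0.0, spec.de_effect_sd, size=n_de)
    gene_effects = pd.DataFrame(
        effects, index=[f"G{g:04d}" for g in range(spec.n_genes)], columns=class_names
    )

    gene_index_of_exon = np.repeat(np.arange(spec.n_genes), counts)
    log2x = (
        gene_base[gene_index_of_exon][:, None]
        + exon_offset[:, None]
        + np.zeros((n_exons, n_samples))
    )
    for j, cname in enumerate(class_names):
        log2x[:, class_idx[cname]] += effects[gene_index_of_exon, j][:, None]

    # planted events: shift affected exons in the affected class only
    exon_global = {}
    off = 0
    for g in range(spec.n_genes):
        exon_global[g] = np.arange(off, off + int(counts[g]))
        off += int(counts[g])
    for ev in spec.events:
        rows = exon_global[ev.gene_index][list(ev.exon_indices)]
        log2x[np.ix_(rows, class_idx[ev.affected_class])] += ev.delta_fc

    if spec.noise_df is not None:
        noise = rng.standard_t(spec.noise_df, size=(n_exons, n_samples)) * spec.noise_sd
    else:
        noise = rng.normal(0.0, spec.noise_sd, size=(n_exons, n_samples))
    values = np.exp2(log2x + noise)

    if spec.silent_exon_rate > 0:
        silent = rng.random(n_exons) < spec.silent_exon_rate
        values[silent, :] = 0.0
    if spec.dropout_rate > 0:
        values[rng.random((n_exons, n_samples)) < spec.dropout_rate] = 0.0

    matrix = ExonExpressionMatrix(
        exons=tuple(exons),
        values=pd.DataFrame(values, index=[e.exon_id for e in exons], columns=samples),
        scale_state="raw",
    )
    classes = pd.DataFrame({"class": sample_class}, index=pd.Index(samples, name="sample_id"))

    esr1 = np.empty(n_samples)
    erbb2 = np.empty(n_samples)
    for i, cname in enumerate(sample_class):
        if cname == CLASS_HER2:
            erbb2[i] = rng.normal(spec.marker_cn_high_mu, spec.marker_sd)
            hi = rng.random() < 0.4  # HER2+ tumors occur on both ER backgrounds
            esr1[i] = rng.normal(spec.marker_high_mu if hi else spec.marker_low_mu, spec.marker_sd)
        elif cname == CLASS_ER_POS:
            erbb2[i] = rng.normal(spec.marker_cn_low_mu, spec.marker_sd)
            esr1[i] = rng.normal(spec.marker_high_mu, spec.marker_sd)
        elif cname == CLASS_ER_NEG:
            erbb2[i] = rng.normal(spec.marker_cn_low_mu, spec.marker_sd)
            esr1[i] = rng.normal(spec.marker_low_mu, spec.marker_sd)
        else:  # NBS or custom classes carry no tumor markers
            erbb2[i] = np.nan
            esr1[i] = np.nan
    markers = pd.DataFrame(
        {"esr1_expr": esr1, "erbb2_focal_cn": erbb2},
        index=pd.Index(samples, name="sample_id"),
    )

    return SyntheticDataset(
        matrix=matrix, classes=classes, markers=markers, spec=spec, gene_effects=gene_effects
    )


def evaluate_calls(callset: DEUCallSet, truth: pd.Series) -> dict[str, float]:
    """Confusion-matrix metrics of final exon calls against planted truth.

    A true positive requires the called sign to match the planted sign.
    Exons never analyzable (excluded in every trial) are counted apart and
    omitted from the denominator of specificity.
    """
    calls = callset.exon_table["final_call"]
    if set(calls.index) != set(truth.index):
        raise ValueError("callset and truth cover different exon universes")
    truth = truth.reindex(calls.index)
    analyzable = callset.exon_table["n_excluded"] < callset.config.n_trials
    tp = int(((calls != 0) & (calls == truth)).sum())
    fp = int(((calls != 0) & (calls != truth)).sum())
    fn = int(((truth != 0) & (calls == 0)).sum())
    tn = int(((truth == 0) & (calls == 0) & analyzable).sum())
    n_pos_truth = int((truth != 0).sum())
    n_called = tp + fp
    metrics = {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "n_truth_events": n_pos_truth,
        "n_called": n_called,
        "n_unanalyzable": int((~analyzable).sum()),
        "sensitivity": tp / n_pos_truth if n_pos_truth else float("nan"),
        "precision": tp / n_called if n_called else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
    }
    return metrics
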