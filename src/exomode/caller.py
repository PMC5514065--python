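"""The resampled trial engine for differential exon usage calling.

For one ordered class comparison (A vs B) the procedure is:

1. Draw ``n_subdatasets`` random 60% subsamples of each class.
2. In every sub-dataset, estimate each exon's *mode expression* (tallest
   KDE peak of its normalized log-expression across the subsample);
   exons whose density has several peaks of comparable height have no
   valid mode there.
3. A *trial* pairs one A sub-dataset with one B sub-dataset (the full
   Cartesian product, so ``n_subdatasets**2`` trials).  Per exon the
   log2 fold change is ``mode_A - mode_B``; exons with an invalid mode
   on either side, or with both modes near zero, are excluded from that
   trial.  A gene with fewer than ``min_valid_exons`` usable exons is
   excluded from the trial entirely.
4. Within a gene and trial, the KDE of the exon fold changes is
   decomposed into peaks.  Exons in the tallest peak's basin (between
   the adjacent density minima) are labeled 0 — they carry only the
   gene-level scaling.  Exons in basins right of it are +1 (unusually
   high fold change), left of it -1.
5. Each exon's score over all trials is ``(#trials +1) - (#trials -1)``.
   Exons whose score lies beyond ``sd_threshold`` standard deviations
   from the mean score of all analyzable exons receive a final call.
6. Per trial the location of the gene density's global maximum records
   whether the gene as a whole went up (>1 log2 unit), down (<-1) or
   stayed similar; the majority over valid trials is the gene's
   direction call.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .density import KDEConfig, estimate_density, find_peaks, mode_expression
from .io import ExonExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CallerConfig",
    "TrialLabeling",
    "DEUCallSet",
    "make_subdatasets",
    "subdataset_modes",
    "trial_fold_changes",
    "label_exons",
    "run_trials",
    "call_exons",
    "gene_directions",
    "run_comparison",
]


@dataclass(frozen=True)
class CallerConfig:
    """All knobs of the trial engine.

    subsample_fraction
        Fraction of each class drawn (without replacement) per sub-dataset.
    n_subdatasets
        Sub-datasets per class; the trial count is its square.
    min_valid_exons
        Genes with fewer valid fold changes in a trial are skipped that trial.
    near_zero_epsilon
        Modes below this (log2 units) in *both* classes mean "unexpressed
        on both sides" and the exon is excluded from the trial.
    sd_threshold
        Final calls require |score - mean| > sd_threshold * sd.
    gene_de_threshold
        Gene up/down per trial when the density's global max exceeds +/- this.
    """

    subsample_fraction: float = 0.6
    n_subdatasets: int = 100
    min_valid_exons: int = 5
    near_zero_epsilon: float = 1.0
    sd_threshold: float = 3.0
    gene_de_threshold: float = 1.0
    seed: int = 0
    kde: KDEConfig = field(default_factory=KDEConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.n_subdatasets < 1:
            raise ValueError("n_subdatasets must be >= 1")
        if self.min_valid_exons < 2:
            raise ValueError("min_valid_exons must be >= 2")
        if self.near_zero_epsilon < 0:
            raise ValueError("near_zero_epsilon must be >= 0")
        if not self.sd_threshold >= 0:
            raise ValueError("sd_threshold must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.n_subdatasets**2

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass(frozen=True)
class TrialLabeling:
    """Per-gene outcome of one trial: exon labels and the dominant-peak location.

    ``labels`` aligns with the exon order passed to :func:`label_exons`
    and takes values -1/0/+1.  ``peak_x`` is the x-location of the global
    density maximum (used for the gene's up/down record).
    """

    labels: np.ndarray
    peak_x: float


@dataclass(frozen=True)
class DEUCallSet:
    """Aggregated result of one ordered class comparison.

    Fold-change orientation is ``class_a - class_b`` throughout.
    ``exon_table`` columns: gene_id, n_plus, n_minus, n_zero, n_excluded,
    score, final_call; ``gene_table`` columns: direction, consistency,
    n_valid_trials.
    """

    class_a: str
    class_b: str
    exon_table: pd.DataFrame
    gene_table: pd.DataFrame
    score_mean: float
    score_sd: float
    config: CallerConfig

    @property
    def called(self) -> pd.DataFrame:
        return self.exon_table[self.exon_table["final_call"] != 0]

    def write(self, prefix: str) -> list[str]:
        """Write calls TSV, gene TSV, BED of called exons, and a JSON manifest."""
        from . import __version__
        from .io import ExonRecord

        paths = []
        calls_path = f"{prefix}.calls.tsv"
        out = self.exon_table.copy()
        out.index.name = "exon_id"
        out.to_csv(calls_path, sep="\t")
        paths.append(calls_path)

        genes_path = f"{prefix}.genes.tsv"
        g = self.gene_table.copy()
        g.index.name = "gene_id"
        g.to_csv(genes_path, sep="\t")
        paths.append(genes_path)

        bed_path = f"{prefix}.called.bed"
        with open(bed_path, "w") as fh:
            for exon_id, row in self.called.iterrows():
                rec = ExonRecord.from_id(str(exon_id))
                bed_score = min(abs(int(row["score"])), 1000)
                fh.write(
                    f"{rec.chrom}\t{rec.start}\t{rec.end}\t{row['gene_id']}\t{bed_score}\t.\n"
                )
        paths.append(bed_path)

        manifest_path = f"{prefix}.manifest.json"
        manifest = {
            "tool": "exomode",
            "version": __version__,
            "comparison": [self.class_a, self.class_b],
            "config": self.config.to_dict(),
            "score_mean": self.score_mean,
            "score_sd": self.score_sd,
            "n_exons": int(len(self.exon_table)),
            "n_called": int(len(self.called)),
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        paths.append(manifest_path)
        return paths


def _class_rng(seed: int, sample_ids: Sequence[str]) -> np.random.Generator:
    # keyed by the class's sample content, not its A/B role, so that the
    # same class yields the same sub-datasets in either comparison
    # orientation (mirrored-pairing antisymmetry)
    tag = zlib.crc32("\x1f".join(sorted(map(str, sample_ids))).encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, tag])


def make_subdatasets(
    sample_ids: Sequence[str], config: CallerConfig
) -> list[list[str]]:
    """Draw ``n_subdatasets`` subsample id-lists without replacement.

    Size is ``round(subsample_fraction * n)``, at least 2.  Deterministic
    given the seed and the class membership (order of ``sample_ids`` does
    not matter).
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 4:
        raise ValueError(f"class has {n} samples; at least 4 required")
    k = max(2, round(config.subsample_fraction * n))
    rng = _class_rng(config.seed, ids)
    ids_sorted = sorted(map(str, ids))
    return [list(rng.choice(ids_sorted, size=k, replace=False)) for _ in range(config.n_subdatasets)]


def subdataset_modes(
    values: pd.DataFrame, subdatasets: Sequence[Sequence[str]], config: CallerConfig
) -> np.ndarray:
    """Mode expression per (exon, sub-dataset); NaN where the mode is invalid.

    ``values`` is the normalized-log matrix restricted to one class.
    Returns an array of shape (n_exons, n_subdatasets).
    """
    arr = values.to_numpy()
    cols = {s: i for i, s in enumerate(values.columns)}
    out = np.full((arr.shape[0], len(subdatasets)), np.nan)
    for j, sub in enumerate(subdatasets):
        idx = [cols[s] for s in sub]
        block = arr[:, idx]
        for i in range(block.shape[0]):
            est = mode_expression(block[i], config.kde)
            if est.valid:
                out[i, j] = est.mode
    return out


def trial_fold_changes(
    modes_a: np.ndarray, modes_b: np.ndarray, config: CallerConfig
) -> np.ndarray:
    """Per-exon log2 FC for one trial; NaN where the exon is excluded.

    Exclusion reasons: invalid mode on either side, or both modes below
    ``near_zero_epsilon`` (unexpressed in both sub-datasets).
    """
    fc = modes_a - modes_b
    eps = config.near_zero_epsilon
    near_zero_both = (modes_a < eps) & (modes_b < eps)
    fc = np.where(near_zero_both, np.nan, fc)
    return fc


def label_exons(fold_changes: np.ndarray, kde: KDEConfig | None = None) -> TrialLabeling:
    """Decompose a gene's exon fold changes into 0 / +1 / -1 labels.

    The tallest peak of the FC density is the gene-level scaling; exons in
    its basin (between the adjacent density minima) are 0.  Exons beyond
    the right minimum are +1, beyond the left minimum -1.  A unimodal (or
    degenerate) density labels every exon 0.
    """
    kde = kde or KDEConfig()
    fc = np.asarray(fold_changes, dtype=float)
    curve = estimate_density(fc, kde)
    if curve.degenerate:
        return TrialLabeling(labels=np.zeros(fc.size, dtype=np.int8), peak_x=float(curve.grid[0]))
    maxima, minima = find_peaks(curve, kde.prominence_floor)
    heights = [h for _, h in maxima]
    top = int(np.argmax(heights))  # first of equals: deterministic
    peak_x = maxima[top][0]
    left = minima[top - 1] if top > 0 else -np.inf
    right = minima[top] if top < len(maxima) - 1 else np.inf
    labels = np.zeros(fc.size, dtype=np.int8)
    labels[fc > right] = 1
    labels[fc < left] = -1
    return TrialLabeling(labels=labels, peak_x=float(peak_x))


def run_trials(
    matrix: ExonExpressionMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    config: CallerConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate all sub-dataset pairs and tally labels per exon.

    Returns ``(tallies, gene_trials)``: tallies indexed by exon_id with
    columns gene_id, n_plus, n_minus, n_zero, n_excluded; gene_trials
    indexed by gene_id with columns n_up, n_down, n_similar (per-trial
    gene direction records over the trials in which the gene was analyzed).
    """
    if matrix.scale_state != "normalized_log":
        raise ValueError("run_trials expects a normalized-log matrix")
    gene_ids = matrix.gene_ids
    if gene_ids.isna().any():
        raise ValueError("all exons must have a gene_id (run map_exons_to_genes)")

    subs_a = make_subdatasets(samples_a, config)
    subs_b = make_subdatasets(samples_b, config)
    modes_a = subdataset_modes(matrix.values[list(samples_a)], subs_a, config)
    modes_b = subdataset_modes(matrix.values[list(samples_b)], subs_b, config)

    n_exons = len(matrix.exons)
    n_plus = np.zeros(n_exons, dtype=np.int64)
    n_minus = np.zeros(n_exons, dtype=np.int64)
    n_zero = np.zeros(n_exons, dtype=np.int64)

    genes = gene_ids.to_numpy()
    gene_order = list(dict.fromkeys(genes))
    gene_rows = {g: np.nonzero(genes == g)[0] for g in gene_order}
    dir_counts = {g: [0, 0, 0] for g in gene_order}  # up, down, similar

    thr = config.gene_de_threshold
    for ia, ib in product(range(config.n_subdatasets), range(config.n_subdatasets)):
        fc = trial_fold_changes(modes_a[:, ia], modes_b[:, ib], config)
        valid = ~np.isnan(fc)
        for g in gene_order:
            rows = gene_rows[g]
            vrows = rows[valid[rows]]
            if vrows.size < config.min_valid_exons:
                continue  # gene excluded this trial; its exons stay "excluded"
            lab = label_exons(fc[vrows], config.kde)
            n_plus[vrows] += lab.labels == 1
            n_minus[vrows] += lab.labels == -1
            n_zero[vrows] += lab.labels == 0
            c = dir_counts[g]
            if lab.peak_x > thr:
                c[0] += 1
            elif lab.peak_x < -thr:
                c[1] += 1
            else:
                c[2] += 1

    n_trials = config.n_trials
    tallies = pd.DataFrame(
        {
            "gene_id": genes,
            "n_plus": n_plus,
            "n_minus": n_minus,
            "n_zero": n_zero,
            "n_excluded": n_trials - n_plus - n_minus - n_zero,
        },
        index=pd.Index(matrix.exon_ids, name="exon_id"),
    )
    gene_trials = pd.DataFrame(
        [(g, *dir_counts[g]) for g in gene_order],
        columns=["gene_id", "n_up", "n_down", "n_similar"],
    ).set_index("gene_id")
    return tallies, gene_trials


def call_exons(tallies: pd.DataFrame, config: CallerConfig) -> tuple[pd.DataFrame, float, float]:
    """Score exons and call those beyond the standard-deviation threshold.

    score = n_plus - n_minus.  Mean and (population) SD are computed over
    exons analyzable in at least one trial; exons never analyzed keep
    final_call 0 and are identifiable by n_excluded == n_trials.
    """
    out = tallies.copy()
    out["score"] = out["n_plus"] - out["n_minus"]
    eligible = out["n_excluded"] < config.n_trials
    out["final_call"] = 0
    if eligible.sum() < 2:
        logger.warning("fewer than 2 analyzable exons; no calls made")
        return out, float("nan"), float("nan")
    scores = out.loc[eligible, "score"].to_numpy(dtype=float)
    mu = float(scores.mean())
    sd = float(scores.std(ddof=0))
    if sd == 0.0:
        logger.warning("score distribution has zero spread; no calls made")
        return out, mu, sd
    hi = mu + config.sd_threshold * sd
    lo = mu - config.sd_threshold * sd
    out.loc[eligible & (out["score"] > hi), "final_call"] = 1
    out.loc[eligible & (out["score"] < lo), "final_call"] = -1
    return out, mu, sd


def gene_directions(gene_trials: pd.DataFrame) -> pd.DataFrame:
    """Majority-vote gene direction over valid trials.

    A gene is "up"/"down" when more than half of the trials in which it
    was analyzed recorded the FC-density global maximum above/below the
    gene DE threshold; otherwise "similar".  ``consistency`` is the
    winning fraction (NaN when the gene was never analyzed).
    """
    n_valid = gene_trials[["n_up", "n_down", "n_similar"]].sum(axis=1)
    direction = pd.Series("similar", index=gene_trials.index, name="direction")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_up = gene_trials["n_up"] / n_valid
        frac_down = gene_trials["n_down"] / n_valid
        frac_sim = gene_trials["n_similar"] / n_valid
    direction[frac_up > 0.5] = "up"
    direction[frac_down > 0.5] = "down"
    consistency = pd.concat([frac_up, frac_down, frac_sim], axis=1).max(axis=1)
    return pd.DataFrame(
        {
            "direction": direction,
            "consistency": consistency,
            "n_valid_trials": n_valid.astype(int),
        }
    )


def run_comparison(
    matrix: ExonExpressionMatrix,
    classes: pd.DataFrame,
    class_a: str,
    class_b: str,
    config: CallerConfig,
) -> DEUCallSet:
    """Full pipeline for one ordered comparison (fold changes = A - B)."""
    cls = classes["class"] if "class" in classes.columns else classes.iloc[:, 0]
    samples_a = [s for s in matrix.samples if s in cls.index and cls[s] == class_a]
    samples_b = [s for s in matrix.samples if s in cls.index and cls[s] == class_b]
    if not samples_a or not samples_b:
        raise ValueError(f"no samples found for comparison {class_a!r} vs {class_b!r}")
    tallies, gene_trials = run_trials(matrix, samples_a, samples_b, config)
    exon_table, mu, sd = call_exons(tallies, config)
    gene_table = gene_directions(gene_trials)
    return DEUCallSet(
        class_a=class_a,
        class_b=class_b,
        exon_table=exon_table,
        gene_table=gene_table,
        score_mean=mu,
        score_sd=sd,
        config=config,
    )
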