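"""Evaluation protocols for latent-space similarity search.

Three analyses at configurable scale:

* threshold AUROC — per reference, rank candidates (ground-truth similarity
  >= a minimum filter) by negative latent distance and score how well a
  similarity threshold separates them; mean +- sd over references;
* top-k reproduction — fraction of the exhaustive-search top-k found within
  the N nearest latent neighbours, averaged over references;
* hit identification / ranking — cumulative recall of threshold-similar
  molecules along the latent ranking, and the histogram of exact similarities
  of the top-n latent neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .search import EmbeddedLibrary

logger = logging.getLogger(__name__)


class UndefinedAUROCError(ValueError):
    """Both classes are required for a defined AUROC."""


def auroc(scores, labels) -> float:
    """P(random positive outscores random negative), ties count half.

    Rank-sum (Mann-Whitney) formulation; exact for tied scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUROCError("AUROC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks at ties -> half credit
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class AurocReport:
    thresholds: list
    mean: dict            # threshold -> mean AUROC over references
    sd: dict              # threshold -> sd over references
    n_references: int
    min_similarity: float
    skipped: dict = field(default_factory=dict)  # threshold -> skipped refs

    def to_rows(self) -> list:
        return [{"threshold": t,
                 "mean_auroc": self.mean.get(t),
                 "sd_auroc": self.sd.get(t),
                 "n_used": self.n_references - len(self.skipped.get(t, [])),
                 "skipped": len(self.skipped.get(t, []))}
                for t in self.thresholds]


def _latent_distances(library: EmbeddedLibrary, ref_index: int) -> np.ndarray:
    diffs = library.latents - library.latents[ref_index]
    return np.sqrt((diffs * diffs).sum(axis=1))


def threshold_auroc_protocol(library: EmbeddedLibrary,
                             sims: np.ndarray,
                             reference_indices,
                             thresholds,
                             min_sim: float = 0.40) -> AurocReport:
    """Per-threshold mean +- sd AUROC over reference compounds.

    `sims[i, j]` is the ground-truth similarity between library molecules i
    and j (library order). For each reference: candidates are the other
    molecules with sim >= min_sim; score is negative latent distance; label
    is sim >= threshold. Single-class references are skipped and counted.
    """
    thresholds = sorted(thresholds)
    sims = np.asarray(sims)
    per_threshold: dict = {t: [] for t in thresholds}
    skipped: dict = {t: [] for t in thresholds}
    for ref in reference_indices:
        dist = _latent_distances(library, ref)
        mask = sims[ref] >= min_sim
        mask[ref] = False  # the reference itself is not a candidate
        cand = np.where(mask)[0]
        scores = -dist[cand]
        for t in thresholds:
            labels = sims[ref, cand] >= t
            try:
                per_threshold[t].append(auroc(scores, labels))
            except UndefinedAUROCError:
                skipped[t].append(library.mol_ids[ref])
    mean = {t: float(np.mean(v)) if v else None
            for t, v in per_threshold.items()}
    sd = {t: float(np.std(v, ddof=1)) if len(v) > 1 else None
          for t, v in per_threshold.items()}
    missing = [t for t, v in per_threshold.items() if not v]
    if missing:
        logger.warning("thresholds with no usable reference: %s", missing)
    return AurocReport(thresholds=list(thresholds), mean=mean, sd=sd,
                       n_references=len(list(reference_indices)),
                       min_similarity=min_sim, skipped=skipped)


@dataclass
class RetrievalCurve:
    N_grid: list
    per_reference: np.ndarray   # [n_refs, len(N_grid)]
    mean: np.ndarray            # [len(N_grid)]


def topk_reproduction_curve(library: EmbeddedLibrary, sims: np.ndarray,
                            reference_indices, N_grid,
                            k: int = 10) -> RetrievalCurve:
    """Fraction of the exhaustive-search top-k (by ground-truth similarity,
    excluding the reference itself) found within the N closest latent
    neighbours, for each N in the grid; averaged over references."""
    sims = np.asarray(sims)
    n = len(library)
    if k > n - 1:
        raise ValueError(f"k={k} exceeds library size minus reference")
    N_grid = sorted(N_grid)
    rows = []
    for ref in reference_indices:
        true_top = sorted((j for j in range(n) if j != ref),
                          key=lambda j: (-sims[ref, j], library.mol_ids[j]))[:k]
        dist = _latent_distances(library, ref)
        pred_order = sorted((j for j in range(n) if j != ref),
                            key=lambda j: (dist[j], library.mol_ids[j]))
        fractions = []
        for N in N_grid:
            found = set(pred_order[:N]) & set(true_top)
            fractions.append(len(found) / k)
        rows.append(fractions)
    per_ref = np.array(rows, dtype=np.float64)
    return RetrievalCurve(N_grid=list(N_grid), per_reference=per_ref,
                          mean=per_ref.mean(axis=0))


def hit_identification_curve(library: EmbeddedLibrary, sims: np.ndarray,
                             ref_index: int, sim_threshold: float = 0.5,
                             N_max: int | None = None) -> np.ndarray:
    """Cumulative recall of threshold-similar molecules within the n nearest
    latent neighbours, n = 1..N_max; non-decreasing by construction."""
    sims = np.asarray(sims)
    n = len(library)
    N_max = N_max or (n - 1)
    similars = {j for j in range(n)
                if j != ref_index and sims[ref_index, j] >= sim_threshold}
    if not similars:
        raise ValueError(
            f"no library molecule with sim >= {sim_threshold} to "
            f"{library.mol_ids[ref_index]}")
    dist = _latent_distances(library, ref_index)
    pred_order = sorted((j for j in range(n) if j != ref_index),
                        key=lambda j: (dist[j], library.mol_ids[j]))
    recall = np.empty(N_max, dtype=np.float64)
    hits = 0
    for rank, j in enumerate(pred_order[:N_max]):
        hits += j in similars
        recall[rank] = hits / len(similars)
    if N_max > len(pred_order):
        recall[len(pred_order):] = recall[len(pred_order) - 1]
    return recall


def ranking_histogram(library: EmbeddedLibrary, sims: np.ndarray,
                      ref_index: int, top_n: int,
                      bin_width: float = 0.05) -> tuple:
    """Histogram of exact similarities of the top_n latent neighbours.

    Returns (counts, bin_edges); counts sum to top_n.
    """
    sims = np.asarray(sims)
    n = len(library)
    if top_n > n - 1:
        raise ValueError(f"top_n={top_n} exceeds library size minus reference")
    dist = _latent_distances(library, ref_index)
    pred_order = sorted((j for j in range(n) if j != ref_index),
                        key=lambda j: (dist[j], library.mol_ids[j]))
    values = sims[ref_index, pred_order[:top_n]]
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return counts, edges


def choose_references(rng: np.random.Generator, candidate_indices,
                      n_references: int) -> np.ndarray:
    """Seeded draw of reference compounds (validation indices)."""
    candidate_indices = np.asarray(list(candidate_indices))
    n = min(n_references, len(candidate_indices))
    return candidate_indices[rng.choice(len(candidate_indices), size=n,
                                        replace=False)]
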