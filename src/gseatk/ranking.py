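"""Per-gene differential metrics turning a two-class expression matrix into a
ranked gene list.

Class A is the first-named class of the phenotype header (CLS line 2); all
signed metrics are oriented A minus B, so a positive score means higher in
class A.  The same vectorised scorer is reused inside every sample
permutation of the phenotype-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionDataset, RankedList

__all__ = ["MetricSpec", "METRICS", "score_genes", "metric_scores", "rank_ties"]

METRICS = ("signal_to_noise", "t_test", "log2_ratio_of_classes", "difference_of_classes")

#: absolute standard-deviation floor applied together with the relative floor
SD_ABS_FLOOR = 1e-8


@dataclass(frozen=True)
class MetricSpec:
    """Choice of class-separation metric.

    Parameters
    ----------
    name
        One of ``signal_to_noise`` (default), ``t_test``,
        ``log2_ratio_of_classes``, ``difference_of_classes``.
    sd_floor_fraction
        Relative floor on each class standard deviation used by
        ``signal_to_noise``: ``sd := max(sd, sd_floor_fraction * |mean|,
        1e-8)``.  Prevents division blow-ups on near-constant genes.
    """

    name: str = "signal_to_noise"
    sd_floor_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.name not in METRICS:
            raise ValueError(f"unknown metric {self.name!r}; choose from {METRICS}")
        if not (np.isfinite(self.sd_floor_fraction) and self.sd_floor_fraction >= 0):
            raise ValueError("sd_floor_fraction must be finite and >= 0")


def _floored_sd(x: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and floored sample sd (ddof=1) along axis 1."""
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    sd = np.maximum(sd, np.maximum(frac * np.abs(mean), SD_ABS_FLOOR))
    return mean, sd


def metric_scores(
    matrix: np.ndarray, mask_a: np.ndarray, spec: MetricSpec
) -> np.ndarray:
    """Score every gene (row of *matrix*) for class A (``mask_a``) vs class B.

    This is the permutation-hot path: it takes a raw float matrix and a
    boolean sample mask so the phenotype-permutation null can re-score
    shuffled labels without rebuilding dataset objects.
    """
    a = matrix[:, mask_a]
    b = matrix[:, ~mask_a]
    if spec.name == "signal_to_noise":
        mean_a, sd_a = _floored_sd(a, spec.sd_floor_fraction)
        mean_b, sd_b = _floored_sd(b, spec.sd_floor_fraction)
        diff = mean_a - mean_b
        out = diff / (sd_a + sd_b)
        out[diff == 0.0] = 0.0
        return out
    if spec.name == "t_test":
        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
        var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        se = np.sqrt(var_a / a.shape[1] + var_b / b.shape[1])
        se = np.maximum(se, SD_ABS_FLOOR)
        diff = mean_a - mean_b
        out = diff / se
        out[diff == 0.0] = 0.0
        return out
    if spec.name == "log2_ratio_of_classes":
        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
        if np.any(mean_a <= 0) or np.any(mean_b <= 0):
            raise ValueError(
                "log2_ratio_of_classes requires strictly positive class means"
            )
        return np.log2(mean_a / mean_b)
    # difference_of_classes
    return a.mean(axis=1) - b.mean(axis=1)


def score_genes(dataset: ExpressionDataset, spec: MetricSpec | None = None) -> RankedList:
    """Rank all genes of a two-class dataset by a differential metric.

    Requires >= 2 samples per class (>= 3 for ``t_test``).  Output is sorted
    descending by score with ties broken by ascending gene symbol.
    """
    spec = spec or MetricSpec()
    if dataset.phenotypes is None:
        raise ValueError("dataset has no phenotype labels")
    mask_a = dataset.class_mask()
    n_a, n_b = int(mask_a.sum()), int((~mask_a).sum())
    min_n = 3 if spec.name == "t_test" else 2
    if n_a < min_n or n_b < min_n:
        raise ValueError(
            f"metric {spec.name!r} needs >= {min_n} samples per class, "
            f"got {n_a} and {n_b}"
        )
    scores = metric_scores(dataset.values.to_numpy(dtype=float), mask_a, spec)
    return RankedList(dataset.gene_ids, scores)


def rank_ties(entries: list[tuple[str, float]]) -> list[tuple[str, float]]:
    """Order (gene, score) pairs descending by score, ties by ascending symbol.

    The resulting total order is unique for any input, hence invariant to
    the input row order.
    """
    return sorted(entries, key=lambda e: (-e[1], e[0]))
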