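"""Seeded synthetic-data generators for end-to-end testing of enrichment
statistics without any external downloads.

The model is deliberately the simplest one under which both rank-based and
signal-to-noise statistics have known behaviour: i.i.d. Gaussian background
values with an additive mean shift planted into the genes of chosen
"planted" sets.  ``make_expression`` plants the shift into class A of a
two-class matrix; ``make_ranked`` plants it directly into ranking scores.
Every generator is a pure function of its seed and spec, and planted sets
may overlap other sets by chance, as in real libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset, GeneSet, GeneSetLibrary, RankedList

__all__ = ["PlantSpec", "gene_universe", "make_library", "make_expression", "make_ranked"]


@dataclass(frozen=True)
class PlantSpec:
    """Study-condition description for the synthetic generators.

    ``effect_size`` is the planted mean shift in units of ``noise_sd``.
    ``planted_set_ids`` name the library sets that receive the shift; with
    ``planted_set_size`` given, those sets are generated at exactly that
    size instead of drawing from ``set_size_range``.
    """

    universe_size: int = 1000
    n_sets: int = 20
    set_size_range: tuple[int, int] = (15, 50)
    planted_set_ids: tuple[str, ...] = ("SET0000",)
    planted_set_size: int | None = None
    effect_size: float = 1.0
    n_samples_per_class: int = 10
    noise_sd: float = 1.0
    seed: int = 0
    class_names: tuple[str, str] = field(default=("A", "B"))

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi <= self.universe_size):
            raise ValueError(
                f"set_size_range {self.set_size_range} infeasible for a "
                f"universe of {self.universe_size}"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_samples_per_class < 2:
            raise ValueError("need >= 2 samples per class")


def gene_universe(size: int) -> list[str]:
    """Deterministic synthetic gene symbols G00000, G00001, ..."""
    return [f"G{i:05d}" for i in range(size)]


def _set_name(i: int) -> str:
    return f"SET{i:04d}"


def make_library(spec: PlantSpec) -> GeneSetLibrary:
    """Sample ``n_sets`` gene sets, each drawn without replacement from the
    universe, with sizes uniform over ``set_size_range`` (planted sets use
    ``planted_set_size`` when given)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x11B]))
    universe = np.asarray(gene_universe(spec.universe_size))
    lo, hi = spec.set_size_range
    lib = GeneSetLibrary()
    for i in range(spec.n_sets):
        name = _set_name(i)
        if name in spec.planted_set_ids and spec.planted_set_size is not None:
            size = spec.planted_set_size
            if not 1 <= size <= spec.universe_size:
                raise ValueError(f"planted_set_size {size} infeasible")
        else:
            size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        lib.add(GeneSet(name=name, description="synthetic", members=tuple(members)))
    for name in spec.planted_set_ids:
        if spec.n_sets and name not in lib:
            raise ValueError(f"planted set {name!r} not among generated sets")
    return lib


def _planted_genes(spec: PlantSpec, library: GeneSetLibrary) -> set[str]:
    out: set[str] = set()
    for name in spec.planted_set_ids:
        if name in library:
            out.update(library[name].members)
    return out


def make_expression(
    spec: PlantSpec, library: GeneSetLibrary
) -> tuple[ExpressionDataset, list[str]]:
    """Two-class expression matrix with planted differential sets.

    Background values are i.i.d. ``Normal(0, noise_sd^2)``; genes of the
    planted sets are shifted by ``+effect_size * noise_sd`` in class A only.
    Returns the dataset (phenotypes attached) and the label list.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xE27]))
    genes = gene_universe(spec.universe_size)
    n_per = spec.n_samples_per_class
    a_name, b_name = spec.class_names
    labels = [a_name] * n_per + [b_name] * n_per
    samples = [f"{a_name}_{i}" for i in range(n_per)] + [f"{b_name}_{i}" for i in range(n_per)]
    values = rng.normal(0.0, spec.noise_sd, size=(spec.universe_size, 2 * n_per))
    planted = _planted_genes(spec, library)
    if planted:
        idx = [i for i, g in enumerate(genes) if g in planted]
        values[np.asarray(idx)[:, None], :n_per] += spec.effect_size * spec.noise_sd
    dataset = ExpressionDataset(
        pd.DataFrame(values, index=genes, columns=samples),
        phenotypes=labels,
        class_order=(a_name, b_name),
    )
    return dataset, labels


def make_ranked(spec: PlantSpec, library: GeneSetLibrary) -> RankedList:
    """Pre-ranked list with planted signal: scores i.i.d. ``Normal(0, 1)``
    plus ``+effect_size`` on planted-set genes, sorted descending."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x4A9]))
    genes = gene_universe(spec.universe_size)
    scores = rng.normal(0.0, 1.0, size=spec.universe_size)
    planted = _planted_genes(spec, library)
    if planted:
        idx = [i for i, g in enumerate(genes) if g in planted]
        scores[np.asarray(idx)] += spec.effect_size
    return RankedList(genes, scores)
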