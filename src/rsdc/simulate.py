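"""Synthetic expression data: the six joint-effect patterns, plus noise.

The built-in 8-sample x 12-gene binary fixture realises six archetypes of
informative gene pairs:

* Pattern I   — consistent reversal of expression,
* Pattern II  — consistent reversal of relative expression (the pair sits
  on different background levels),
* Pattern III — consistent expression (both genes shift together),
* Pattern IV  — consistent relative expression,
* Pattern V   — heterogeneous sample background (within-class background
  levels alternate across samples, hiding the genes from any
  per-gene threshold),
* Pattern VI  — interaction (the joint state, not either gene alone,
  carries the class).

The seeded generator plants such pattern pairs in multi-class datasets of
configurable size, adds Gaussian jitter around the templates and fills
the matrix with uniform background-noise genes, emulating the small-n /
large-p shape of tumour expression studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ExpressionDataset

__all__ = ["PATTERNS", "SyntheticSpec", "table1_fixture", "generate"]


# per pattern: (positive-class variants, negative-class variants); each
# variant is a (gene_a, gene_b) template level; multi-variant patterns
# alternate across samples within a class
PATTERNS: dict[str, tuple[tuple[tuple[float, float], ...], tuple[tuple[float, float], ...]]] = {
    "I": (((50.0, 100.0),), ((100.0, 50.0),)),
    "II": (((5.0, 100.0),), ((10.0, 50.0),)),
    "III": (((50.0, 50.0),), ((100.0, 100.0),)),
    "IV": (((5.0, 50.0),), ((10.0, 100.0),)),
    "V": (((50.0, 100.0), (5.0, 10.0)), ((100.0, 50.0), (10.0, 5.0))),
    "VI": (((50.0, 50.0), (100.0, 100.0)), ((50.0, 100.0), (100.0, 50.0))),
}


def _pattern_range(pattern: str) -> float:
    pos, neg = PATTERNS[pattern]
    vals = [v for variant in pos + neg for v in variant]
    return max(vals) - min(vals)


def table1_fixture() -> ExpressionDataset:
    """The exact 8 x 12 binary fixture: all six patterns, noise-free.

    Genes G1..G12 hold Patterns I..VI in consecutive pairs; classes are
    "+" (samples s1-s4) and "-" (samples s5-s8).
    """
    pos_a = [50, 100, 5, 100, 50, 50, 5, 50, 50, 100, 50, 50]
    pos_b = [50, 100, 5, 100, 50, 50, 5, 50, 5, 10, 100, 100]
    neg_a = [100, 50, 10, 50, 100, 100, 10, 100, 100, 50, 50, 100]
    neg_b = [100, 50, 10, 50, 100, 100, 10, 100, 10, 5, 100, 50]
    values = np.array(
        [pos_a, pos_b, pos_a, pos_b, neg_a, neg_b, neg_a, neg_b], dtype=float
    )
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(1, 9)],
        gene_ids=[f"G{j}" for j in range(1, 13)],
        values=values,
        labels=["+"] * 4 + ["-"] * 4,
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a planted-pattern dataset; the seed fixes everything.

    ``planted`` lists (pattern, target class) entries, each contributing a
    pair of genes: the target class expresses the pattern's positive
    template, every other class its negative template.  ``jitter_sd``
    defaults to 5 % of each pattern's template range; noise genes are
    i.i.d. uniform on [``noise_low``, ``noise_high``], spanning the
    template levels.
    """

    classes: tuple[str, ...] = ("C1", "C2")
    samples_per_class: int = 20
    planted: tuple[tuple[str, str], ...] = (("I", "C1"),)
    n_noise: int = 0
    noise_low: float = 5.0
    noise_high: float = 110.0
    jitter_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if self.samples_per_class < 1:
            raise ValueError("need at least 1 sample per class")
        for pattern, target in self.planted:
            if pattern not in PATTERNS:
                raise ValueError(
                    f"unknown pattern {pattern!r}; choose from "
                    f"{sorted(PATTERNS)}"
                )
            if target not in self.classes:
                raise ValueError(f"target class {target!r} not in classes")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "classes" in d:
            d["classes"] = tuple(str(c) for c in d["classes"])
        if "planted" in d:
            d["planted"] = tuple(
                (str(p), str(t)) for p, t in d["planted"]
            )
        return cls(**d)


def generate(spec: SyntheticSpec) -> ExpressionDataset:
    """Draw one dataset from a spec; identical specs and seeds match exactly."""
    rng = np.random.default_rng(spec.seed)
    n_per = spec.samples_per_class
    n = n_per * len(spec.classes)
    labels = [c for c in spec.classes for _ in range(n_per)]

    columns: list[np.ndarray] = []
    gene_ids: list[str] = []
    for k, (pattern, target) in enumerate(spec.planted):
        pos_variants, neg_variants = PATTERNS[pattern]
        sd = (
            spec.jitter_sd
            if spec.jitter_sd is not None
            else 0.05 * _pattern_range(pattern)
        )
        col_a = np.empty(n)
        col_b = np.empty(n)
        i = 0
        for cls in spec.classes:
            variants = pos_variants if cls == target else neg_variants
            for s in range(n_per):
                a, b = variants[s % len(variants)]
                col_a[i] = a
                col_b[i] = b
                i += 1
        if sd > 0:
            col_a = col_a + rng.normal(0.0, sd, size=n)
            col_b = col_b + rng.normal(0.0, sd, size=n)
        columns.extend([col_a, col_b])
        gene_ids.extend(
            [f"p{k + 1}_{pattern}_{target}_a", f"p{k + 1}_{pattern}_{target}_b"]
        )

    if spec.n_noise:
        noise = rng.uniform(
            spec.noise_low, spec.noise_high, size=(n, spec.n_noise)
        )
        columns.extend(noise.T)
        width = len(str(spec.n_noise))
        gene_ids.extend(
            f"noise{j + 1:0{width}d}" for j in range(spec.n_noise)
        )

    if not columns:
        raise ValueError("spec yields no genes; plant a pattern or add noise")
    return ExpressionDataset(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        gene_ids=gene_ids,
        values=np.column_stack(columns),
        labels=labels,
        class_order=list(spec.classes),
    )
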