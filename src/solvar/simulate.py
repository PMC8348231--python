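"""Synthetic fixtures: download-free datasets with a planted, learnable label rule.

Real solubility-variant corpora are built from curated literature and deep
mutational scans and cannot be bundled; these generators produce data with
the same *shape* — random canonical-alphabet sequences, several substitutions
per position (so group-atomic splitting is exercised), three-class labels at
roughly the 3136 : 2166 : 1026 decrease/no-effect/increase imbalance of a
curated solubility corpus — plus a planted rule tying labels to features the
models can see, so that learning and feature selection are testable end to
end with known ground truth.

The planted rule operates on the substitution's residue groups and the
neighborhood charge count:

* hydrophobic wild-type replaced by a non-hydrophobic residue → *decrease*;
* non-hydrophobic replaced by hydrophobic → *increase*;
* otherwise: *increase* when the 23-window holds ≥ 8 charged residues,
  else *no_effect*.

``signal`` interpolates between this rule (1.0) and labels drawn blindly
from the class proportions (0.0).  Nothing here is biophysically realistic;
it exists to give the pipeline a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import RESIDUE_GROUPS, neighborhood_counts
from .io import AMINO_ACIDS, CLASSES, LabeledDataset, ProteinRecord, VariantRecord

#: Class proportions of the emulated corpus (decrease, no_effect, increase).
DEFAULT_PROPORTIONS = (3136 / 6328, 2166 / 6328, 1026 / 6328)

_HYDROPHOBIC = RESIDUE_GROUPS["hydrophobic"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic dataset.

    ``class_proportions`` follows the (decrease, no_effect, increase) order
    and is the label distribution of the *noise* component; at high signal
    the planted rule's own class frequencies dominate.  ``variants_per_position``
    draws that many distinct substitutions at each sampled position, giving
    the grouped splitters something to protect.
    """

    n_proteins: int = 10
    length_range: tuple[int, int] = (60, 300)
    n_variants: int = 1000
    class_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    signal: float = 1.0
    variants_per_position: tuple[int, int] = (1, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not 0 <= self.signal <= 1:
            raise ValueError("signal must be in [0, 1]")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")


def _rule_label(sequence: str, position: int, wt: str, mut: str) -> str:
    wt_h, mut_h = wt in _HYDROPHOBIC, mut in _HYDROPHOBIC
    if wt_h and not mut_h:
        return "decrease"
    if mut_h and not wt_h:
        return "increase"
    charged = neighborhood_counts(sequence, position)["ChargedAA"]
    return "increase" if charged >= 8 else "no_effect"


def generate_fixture(spec: FixtureSpec) -> LabeledDataset:
    """Generate a labeled dataset per ``spec``; byte-identical under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    proteins: dict[str, ProteinRecord] = {}
    positions: list[tuple[str, int]] = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = "".join(rng.choice(aa, size=length))
        pid = f"synth{i:03d}"
        proteins[pid] = ProteinRecord(pid, seq)
        positions.extend((pid, p) for p in range(1, length + 1))
    if spec.n_variants > 19 * len(positions):
        raise ValueError(
            f"infeasible spec: {spec.n_variants} variants requested but only "
            f"{19 * len(positions)} distinct substitutions exist")

    order = rng.permutation(len(positions))
    variants: list[VariantRecord] = []
    proportions = np.asarray(spec.class_proportions)
    cursor = 0
    while len(variants) < spec.n_variants and cursor < len(positions):
        pid, pos = positions[order[cursor]]
        cursor += 1
        seq = proteins[pid].sequence
        wt = seq[pos - 1]
        k = int(rng.integers(spec.variants_per_position[0],
                             spec.variants_per_position[1] + 1))
        muts = rng.choice([a for a in AMINO_ACIDS if a != wt],
                          size=min(k, spec.n_variants - len(variants)), replace=False)
        for mut in muts:
            if rng.random() < spec.signal:
                label = _rule_label(seq, pos, wt, mut)
            else:
                label = CLASSES[rng.choice(3, p=proportions)]
            variants.append(VariantRecord(pid, pos, wt, str(mut), label))
    if len(variants) < spec.n_variants:
        raise ValueError("infeasible spec: ran out of positions before n_variants")
    ds = LabeledDataset(proteins, variants)
    ds.validate()
    return ds


def planted_signal_matrix(
    n: int = 500,
    n_noise: int = 50,
    seed: int = 0,
    effect: float = 2.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Tabular fixture for feature selection: one informative column among noise.

    Returns ``(X, y)`` where y is balanced binary, the ``informative`` column
    is shifted by ``effect`` standard deviations between classes, and the
    ``noise_*`` columns are independent standard normals.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    informative = rng.normal(size=n) + effect * y
    noise = rng.normal(size=(n, n_noise))
    X = pd.DataFrame(noise, columns=[f"noise_{i:02d}" for i in range(n_noise)])
    X.insert(rng.integers(0, n_noise + 1), "informative", informative)
    return X, y


def write_synthetic_aaindex(path, accessions: list[str] | None = None, seed: int = 0) -> None:
    """Write a synthetic AAindex1-format file (random values, real-looking layout).

    The scale *values* are uniform random draws, not measured properties; the
    accession strings default to the amino-acid scales named by the shipped
    feature subsets so that download-free pipelines can assemble those
    subsets.  For scientific use supply a genuine AAindex flat file instead.
    """
    from .features import FINAL_FEATURES

    if accessions is None:
        accessions = [f for f in FINAL_FEATURES
                      if not f.startswith("AA20D.") and f not in
                      ("NonPolarAA", "PolarAA", "ChargedAA", "PosAA", "NegAA", "length")]
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for acc in accessions:
            vals = np.round(rng.uniform(-5, 5, size=20), 3)
            fh.write(f"H {acc}\n")
            fh.write("D synthetic stand-in scale (random values; not the published entry)\n")
            fh.write("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n")
            for half in (vals[:10], vals[10:]):
                fh.write("   " + "  ".join(f"{v:6.3f}" for v in half) + "\n")
            fh.write("//\n")
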