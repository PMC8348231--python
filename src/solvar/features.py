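"""Featurization of (protein, substitution) pairs.

The feature space has four categories:

* **amino_acid** — one scalar per AAindex property scale, encoded as the
  mutant-minus-wild-type difference ``value(mut) − value(wt)``.  This gives a
  substitution-level scalar per scale that is antisymmetric under swapping
  the residues.
* **variation_type** — 436 indicators: a 20×20 one-hot over ordered
  (wt, mut) residue pairs plus a 6×6 one-hot over ordered residue-group
  pairs (hydrophobic / negatively charged / positively charged /
  conformational / polar / other).
* **neighborhood** — 25 counts over the 23-residue window centered on the
  substitution site (11 residues each side plus the site itself, truncated
  at the sequence ends): one count per residue type (``AA20D.*``) and five
  physicochemical summaries (NonPolarAA, PolarAA, ChargedAA, PosAA, NegAA).
* **protein_type** — the chain length.

Two conservation features (a SIFT-style deleteriousness score and the number
of homology-search hits) exist as an optional stub that emits declared
missing values; they require external homology searches and are excluded by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, AAindexTable, LabeledDataset, ProteinRecord, VariantRecord, ValidationError

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Six disjoint residue groups covering the 20-letter alphabet, used for the
#: 6x6 substitution-type matrix.
RESIDUE_GROUPS: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("VILFMWYC"),
    "negative": frozenset("DE"),
    "positive": frozenset("RKH"),
    "conformational": frozenset("GP"),
    "polar": frozenset("NQS"),
    "other": frozenset("AT"),
}
_GROUP_ORDER = list(RESIDUE_GROUPS)
_GROUP_OF = {aa: g for g, members in RESIDUE_GROUPS.items() for aa in members}

#: Residue classes for the five neighborhood summaries.  A standard
#: biochemistry partition; configurable via ``FeatureSpace`` because usage
#: varies between textbooks (C and G are the usual points of disagreement).
NEIGHBOR_CLASSES: dict[str, frozenset[str]] = {
    "NonPolarAA": frozenset("AVLIPFMWG"),
    "PolarAA": frozenset("STCYNQ"),
    "PosAA": frozenset("KRH"),
    "NegAA": frozenset("DE"),
}

#: Half-width of the neighborhood window (23 positions total).
WINDOW_HALF = 11

#: Feature names used by the decreasing/not-decreasing layer of the shipped
#: two-layer model, in descending importance.
LAYER1_FEATURES = [
    "FUKS010101", "JOND920102", "PONP800107", "NonPolarAA", "PolarAA",
    "QIAN880134", "AA20D.T", "PosAA", "AA20D.L", "GEOR030102",
    "OOBM850102", "length", "AA20D.I", "AA20D.P", "KOSJ950115",
    "ARGP820102", "PRAM820103", "AA20D.V", "ZIMJ680104", "CHOP780209",
]

#: Feature names used by the increasing/no-effect layer, in descending importance.
LAYER2_FEATURES = [
    "VASM830102", "PRAM820103", "DAYM780201", "ChargedAA", "DOSZ010102",
    "NonPolarAA", "PRAM820101", "BROC820102", "PolarAA", "MIRL960101",
    "AA20D.D", "VASM830101", "SUYM030101", "length", "FASG760103",
    "CHOP780213", "AA20D.L", "LIFS790102", "PosAA", "AA20D.G",
]

#: Union of the two layer sets (34 names; six are shared between layers).
FINAL_FEATURES = LAYER1_FEATURES + [f for f in LAYER2_FEATURES if f not in LAYER1_FEATURES]

CONSERVATION_FEATURES = ["SIFT.score", "SIFT.hits"]


def residue_group(aa: str) -> str:
    """Name of the six-way substitution group containing residue ``aa``."""
    try:
        return _GROUP_OF[aa]
    except KeyError:
        raise ValidationError(f"non-canonical residue {aa!r}") from None


def aaindex_delta_features(wt: str, mut: str, table: AAindexTable) -> dict[str, float]:
    """Mutant-minus-wild-type difference for every scale in ``table``."""
    return {acc: vals[mut] - vals[wt] for acc, vals in table.entries.items()}


def substitution_onehot_400(wt: str, mut: str) -> dict[str, float]:
    """400 indicators over ordered (wt, mut) pairs; exactly one is 1."""
    if wt not in _AA_INDEX or mut not in _AA_INDEX:
        raise ValidationError(f"non-canonical residue in ({wt!r}, {mut!r})")
    out = {f"SUB.{a}{b}": 0.0 for a in AMINO_ACIDS for b in AMINO_ACIDS}
    out[f"SUB.{wt}{mut}"] = 1.0
    return out


def group_onehot_36(wt: str, mut: str) -> dict[str, float]:
    """36 indicators over ordered residue-group pairs; diagonal cells allowed."""
    gw, gm = residue_group(wt), residue_group(mut)
    out = {f"GRP.{a}.{b}": 0.0 for a in _GROUP_ORDER for b in _GROUP_ORDER}
    out[f"GRP.{gw}.{gm}"] = 1.0
    return out


def neighborhood_counts(
    sequence: str,
    position: int,
    classes: dict[str, frozenset[str]] = NEIGHBOR_CLASSES,
) -> dict[str, float]:
    """Residue-type and class counts in the 23-window around ``position`` (1-based).

    The window is truncated at the sequence ends (no padding), so interior
    positions have counts summing to 23 and terminal positions to as few as
    12.  The wild-type residue at the substitution site itself is included.
    """
    if not 1 <= position <= len(sequence):
        raise ValidationError(f"position {position} outside sequence of length {len(sequence)}")
    lo = max(0, position - 1 - WINDOW_HALF)
    hi = min(len(sequence), position + WINDOW_HALF)
    window = sequence[lo:hi]
    out = {f"AA20D.{aa}": 0.0 for aa in AMINO_ACIDS}
    for ch in window:
        out[f"AA20D.{ch}"] += 1.0
    for name in ("NonPolarAA", "PolarAA", "PosAA", "NegAA"):
        out[name] = sum(out[f"AA20D.{aa}"] for aa in classes[name])
    out["ChargedAA"] = out["PosAA"] + out["NegAA"]
    # report class summaries in a fixed order
    order = [f"AA20D.{aa}" for aa in AMINO_ACIDS] + [
        "NonPolarAA", "PolarAA", "ChargedAA", "PosAA", "NegAA"]
    return {k: out[k] for k in order}


@dataclass
class FeatureSpace:
    """The full named feature space induced by an AAindex table.

    Parameters
    ----------
    aaindex
        Property scales; one delta feature per retained entry.
    include_conservation
        If True, append the two conservation stub features (emitted as NaN;
        requires external homology data to be meaningful).  Off by default.
    neighbor_classes
        Residue classes behind the five neighborhood summaries.
    """

    aaindex: AAindexTable
    include_conservation: bool = False
    neighbor_classes: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(NEIGHBOR_CLASSES))

    @property
    def names(self) -> list[str]:
        n = list(self.aaindex.entries)
        if self.include_conservation:
            n += CONSERVATION_FEATURES
        n += [f"SUB.{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]
        n += [f"GRP.{a}.{b}" for a in _GROUP_ORDER for b in _GROUP_ORDER]
        n += [f"AA20D.{aa}" for aa in AMINO_ACIDS]
        n += ["NonPolarAA", "PolarAA", "ChargedAA", "PosAA", "NegAA", "length"]
        return n

    @property
    def provenance(self) -> dict[str, str]:
        """Feature name -> category."""
        out = {acc: "amino_acid" for acc in self.aaindex.entries}
        if self.include_conservation:
            out.update({f: "conservation" for f in CONSERVATION_FEATURES})
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                out[f"SUB.{a}{b}"] = "variation_type"
        for a in _GROUP_ORDER:
            for b in _GROUP_ORDER:
                out[f"GRP.{a}.{b}"] = "variation_type"
        for aa in AMINO_ACIDS:
            out[f"AA20D.{aa}"] = "neighborhood"
        for s in ("NonPolarAA", "PolarAA", "ChargedAA", "PosAA", "NegAA"):
            out[s] = "neighborhood"
        out["length"] = "protein_type"
        return out

    def __len__(self) -> int:
        return len(self.names)

    def vector(
        self,
        protein: ProteinRecord,
        variant: VariantRecord,
        subset: list[str] | None = None,
    ) -> pd.Series:
        """Assemble the named feature vector for one substitution."""
        if protein.sequence[variant.position - 1] != variant.wt:
            raise ValidationError(
                f"{variant.protein_id} {variant.notation}: wild-type mismatch with sequence")
        vals: dict[str, float] = {}
        vals.update(aaindex_delta_features(variant.wt, variant.mut, self.aaindex))
        if self.include_conservation:
            vals.update({f: float("nan") for f in CONSERVATION_FEATURES})
        vals.update(substitution_onehot_400(variant.wt, variant.mut))
        vals.update(group_onehot_36(variant.wt, variant.mut))
        vals.update(neighborhood_counts(protein.sequence, variant.position,
                                        self.neighbor_classes))
        vals["length"] = float(len(protein))
        series = pd.Series(vals, dtype=float).reindex(self.names)
        if subset is not None:
            missing = [s for s in subset if s not in series.index]
            if missing:
                raise KeyError(f"requested features absent from space: {missing}")
            series = series.reindex(subset)
        return series

    def matrix(self, dataset: LabeledDataset, subset: list[str] | None = None) -> pd.DataFrame:
        """Feature matrix for a whole dataset (rows follow dataset order).

        Vectorized over variants: AAindex deltas and one-hots are pure
        residue-pair lookups; only the window counts touch the sequence.
        """
        names = self.names
        n = len(dataset.variants)
        wt_idx = np.array([_AA_INDEX[v.wt] for v in dataset.variants])
        mut_idx = np.array([_AA_INDEX[v.mut] for v in dataset.variants])

        blocks: list[pd.DataFrame] = []
        if self.aaindex.entries:
            scale = np.array(
                [[vals[aa] for aa in AMINO_ACIDS] for vals in self.aaindex.entries.values()])
            delta = scale[:, mut_idx] - scale[:, wt_idx]  # (n_entries, n)
            blocks.append(pd.DataFrame(delta.T, columns=list(self.aaindex.entries)))
        if self.include_conservation:
            blocks.append(pd.DataFrame(np.nan, index=range(n), columns=CONSERVATION_FEATURES))

        sub = np.zeros((n, 400))
        sub[np.arange(n), wt_idx * 20 + mut_idx] = 1.0
        blocks.append(pd.DataFrame(
            sub, columns=[f"SUB.{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]))

        gidx = {g: i for i, g in enumerate(_GROUP_ORDER)}
        gw = np.array([gidx[_GROUP_OF[v.wt]] for v in dataset.variants])
        gm = np.array([gidx[_GROUP_OF[v.mut]] for v in dataset.variants])
        grp = np.zeros((n, 36))
        grp[np.arange(n), gw * 6 + gm] = 1.0
        blocks.append(pd.DataFrame(
            grp, columns=[f"GRP.{a}.{b}" for a in _GROUP_ORDER for b in _GROUP_ORDER]))

        neigh = np.empty((n, 25))
        neigh_cols = None
        for i, v in enumerate(dataset.variants):
            counts = neighborhood_counts(
                dataset.proteins[v.protein_id].sequence, v.position, self.neighbor_classes)
            if neigh_cols is None:
                neigh_cols = list(counts)
            neigh[i] = list(counts.values())
        blocks.append(pd.DataFrame(neigh, columns=neigh_cols))

        blocks.append(pd.DataFrame(
            {"length": [float(len(dataset.proteins[v.protein_id])) for v in dataset.variants]}))

        X = pd.concat(blocks, axis=1)[names]
        if subset is not None:
            missing = [s for s in subset if s not in X.columns]
            if missing:
                raise KeyError(f"requested features absent from space: {missing}")
            X = X[subset]
        return X


def export_feature_matrix(X: pd.DataFrame, path) -> None:
    """Write a feature matrix as TSV with the feature names as header."""
    X.to_csv(path, sep="\t", index=False)
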