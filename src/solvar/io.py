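"""Data model and parsers: protein sequences, variant notation, labeled datasets, AAindex scales.

Coordinates are 1-based throughout the public interface, following the
protein-variant convention (``L123S`` means the leucine at position 123, with
``sequence[122]`` in Python indexing, is replaced by serine).  Only the 20
canonical one-letter residue codes are accepted; ambiguity codes (B, J, O, U,
X, Z) are rejected because every downstream feature table is defined over the
canonical alphabet.
"""

from __future__ import annotations

import io as _stdio
import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: Canonical one-letter amino acid alphabet, alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: The three solubility outcome classes, in fixed report order.
CLASSES = ("decrease", "no_effect", "increase")

#: Order of residues on the two value rows of an AAindex1 entry
#: (I line header: A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V).
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


class ValidationError(ValueError):
    """Raised when an input record violates a data-model invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 canonical residues."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in _AA_SET:
                raise ValidationError(
                    f"protein {self.id!r}: illegal residue {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    """One single amino acid substitution on one protein.

    ``position`` is 1-based; ``wt`` must match the protein sequence at that
    position (checked by :func:`load_dataset_tsv` and the featurizer, since
    the record itself does not hold the sequence).
    """

    protein_id: str
    position: int
    wt: str
    mut: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.wt not in _AA_SET or self.mut not in _AA_SET:
            raise ValidationError(
                f"{self.protein_id} {self.notation}: non-canonical residue"
            )
        if self.wt == self.mut:
            raise ValidationError(
                f"{self.protein_id} {self.notation}: not a substitution (wt == mut)"
            )
        if self.position < 1:
            raise ValidationError(f"{self.protein_id}: position must be >= 1")
        if self.label is not None and self.label not in CLASSES:
            raise ValidationError(
                f"{self.protein_id} {self.notation}: unknown label {self.label!r}"
            )

    @property
    def notation(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @property
    def group_key(self) -> tuple[str, int]:
        """(protein, position) — the atomic unit for leakage-safe splits."""
        return (self.protein_id, self.position)


@dataclass
class AAindexTable:
    """Named amino acid property scales: accession -> {residue: value}."""

    entries: dict[str, dict[str, float]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def accessions(self) -> list[str]:
        return list(self.entries)


@dataclass
class LabeledDataset:
    """Proteins plus labeled variants, with class bookkeeping."""

    proteins: dict[str, ProteinRecord]
    variants: list[VariantRecord]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for v in self.variants:
            if v.label is not None:
                counts[v.label] += 1
        return counts

    def __len__(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        """Check every variant against its protein sequence."""
        for i, v in enumerate(self.variants):
            prot = self.proteins.get(v.protein_id)
            if prot is None:
                raise ValidationError(
                    f"variant {i} ({v.protein_id} {v.notation}): unknown protein id"
                )
            if v.position > len(prot):
                raise ValidationError(
                    f"{v.protein_id} {v.notation}: position beyond sequence "
                    f"length {len(prot)}"
                )
            if prot.sequence[v.position - 1] != v.wt:
                raise ValidationError(
                    f"{v.protein_id} {v.notation}: wild-type {v.wt} does not match "
                    f"sequence residue {prot.sequence[v.position - 1]}"
                )

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset(self.proteins, [self.variants[i] for i in indices])


def parse_fasta(text: str) -> list[ProteinRecord]:
    """Parse FASTA text into validated protein records.

    Sequences are uppercased and whitespace-stripped; an illegal residue
    raises :class:`ValidationError` naming the offending position.
    """
    if not text.strip():
        raise ValidationError("empty FASTA input")
    records = []
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "").replace("\t", "")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValidationError("no FASTA records found")
    return records


def read_fasta(path) -> list[ProteinRecord]:
    with open(path) as fh:
        return parse_fasta(fh.read())


_VARIANT_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")


def parse_variant(text: str) -> tuple[str, int, str]:
    """Parse ``L123S``-style substitution notation into ``(wt, position, mut)``.

    A leading HGVS-style ``p.`` prefix is tolerated and stripped.
    """
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise ValidationError(f"malformed variant notation: {text!r}")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    if wt not in _AA_SET or mut not in _AA_SET:
        raise ValidationError(f"{text!r}: non-canonical residue letter")
    if wt == mut:
        raise ValidationError(f"{text!r}: wild-type and mutant are identical")
    if pos < 1:
        raise ValidationError(f"{text!r}: position must be >= 1")
    return wt, pos, mut


_COLUMN_ALIASES = {
    "protein_id": {"protein_id", "protein", "id", "acc", "accession", "seq_id"},
    "variant": {"variant", "substitution", "aas", "mutation", "variation"},
    "label": {"label", "class", "effect", "solubility", "outcome"},
}

_LABEL_ALIASES = {
    "decrease": "decrease", "decreasing": "decrease", "-": "decrease", "dec": "decrease",
    "no_effect": "no_effect", "no": "no_effect", "none": "no_effect",
    "neutral": "no_effect", "no effect": "no_effect",
    "increase": "increase", "increasing": "increase", "+": "increase", "inc": "increase",
}


def _map_columns(header: list[str]) -> dict[str, int]:
    mapping = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for i, col in enumerate(header):
            if col.strip().lower() in aliases:
                mapping[canon] = i
                break
        else:
            raise ValidationError(f"dataset TSV: no column recognizable as {canon!r}")
    return mapping


def load_dataset_tsv(path, fasta_path, *, on_duplicate: str = "error") -> LabeledDataset:
    """Load the canonical 3-column dataset TSV plus its companion FASTA.

    Columns (obvious aliases are accepted): protein_id, variant, label.
    ``on_duplicate`` is ``"error"`` (default) or ``"dedup"`` for repeated
    (protein, variant) rows.
    """
    if on_duplicate not in ("error", "dedup"):
        raise ValueError("on_duplicate must be 'error' or 'dedup'")
    proteins = {p.id: p for p in read_fasta(fasta_path)}
    variants: list[VariantRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValidationError(f"{path}: empty dataset file")
    cols = _map_columns(lines[0].split("\t"))
    for row_no, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        pid = parts[cols["protein_id"]].strip()
        var_txt = parts[cols["variant"]].strip()
        label_txt = parts[cols["label"]].strip().lower()
        label = _LABEL_ALIASES.get(label_txt)
        if label is None:
            raise ValidationError(f"{path} row {row_no}: unknown label {label_txt!r}")
        wt, pos, mut = parse_variant(var_txt)
        key = (pid, f"{wt}{pos}{mut}")
        if key in seen:
            if on_duplicate == "error":
                raise ValidationError(f"{path} row {row_no}: duplicate variant {key}")
            continue
        seen.add(key)
        try:
            variants.append(VariantRecord(pid, pos, wt, mut, label))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {row_no}: {exc}") from exc
    ds = LabeledDataset(proteins, variants)
    try:
        ds.validate()
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    return ds


def write_dataset_tsv(dataset: LabeledDataset, tsv_path, fasta_path) -> None:
    """Write a LabeledDataset in the canonical TSV + FASTA form."""
    with open(fasta_path, "w") as fh:
        for p in dataset.proteins.values():
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    with open(tsv_path, "w") as fh:
        fh.write("protein_id\tvariant\tlabel\n")
        for v in dataset.variants:
            fh.write(f"{v.protein_id}\t{v.notation}\t{v.label or ''}\n")


def substitution_spectrum(dataset: LabeledDataset) -> pd.DataFrame:
    """20×20 table of substitution counts: rows = wild-type, columns = mutant."""
    aas = list(AMINO_ACIDS)
    counts = pd.DataFrame(0, index=aas, columns=aas)
    for v in dataset.variants:
        counts.loc[v.wt, v.mut] += 1
    return counts


def parse_aaindex(text: str) -> AAindexTable:
    """Parse the AAindex1 flat-file dialect.

    Each entry starts with an ``H`` accession line; the ``I`` line is followed
    by two rows of ten values (A R N D C Q E G H I / L K M F P S T W Y V).
    Entries with any missing (``NA``) value are dropped; unparseable entries
    are skipped with a warning.
    """
    table = AAindexTable()
    blocks = [b for b in text.split("//") if b.strip()]
    for block in blocks:
        acc = None
        desc = ""
        values: list[float] | None = None
        try:
            lines = block.splitlines()
            i = 0
            while i < len(lines):
                line = lines[i]
                if line.startswith("H "):
                    acc = line[2:].strip()
                elif line.startswith("D "):
                    desc = line[2:].strip()
                elif line.startswith("I "):
                    tokens = (lines[i + 1].split() + lines[i + 2].split())
                    if len(tokens) != 20:
                        raise ValueError(f"expected 20 values, got {len(tokens)}")
                    if any(t.upper() in ("NA", "NA.") for t in tokens):
                        values = None
                        acc_na = acc
                        raise _IncompleteEntry(acc_na)
                    values = [float(t) for t in tokens]
                    i += 2
                i += 1
            if acc is None or values is None:
                raise ValueError("missing H or I record")
        except _IncompleteEntry as exc:
            log.warning("aaindex entry %s dropped: contains NA values", exc.args[0])
            continue
        except (ValueError, IndexError) as exc:
            log.warning("skipping unparseable aaindex block (%s)", exc)
            continue
        residue_order = _AAINDEX_ROW1 + _AAINDEX_ROW2
        table.entries[acc] = dict(zip(residue_order, values))
        table.descriptions[acc] = desc
    if not table.entries:
        raise ValidationError("no usable AAindex entries found")
    log.info("aaindex: retained %d complete entries", len(table.entries))
    return table


class _IncompleteEntry(Exception):
    pass


def load_aaindex(path) -> AAindexTable:
    with open(path) as fh:
        return parse_aaindex(fh.read())


def write_prediction_report(path, rows, *, header_meta: dict | None = None) -> None:
    """Write a prediction report TSV.

    ``rows`` are dicts with keys protein_id, variant, predicted, and any
    score columns; ``header_meta`` is written as ``# key: value`` lines.
    """
    rows = list(rows)
    score_cols = sorted({k for r in rows for k in r} - {"protein_id", "variant", "predicted"})
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("\t".join(["protein_id", "variant", "predicted"] + score_cols) + "\n")
        for r in rows:
            fields = [str(r.get("protein_id", "")), str(r.get("variant", "")),
                      str(r.get("predicted", ""))]
            fields += [f"{r[c]:.6g}" if isinstance(r.get(c), float) else str(r.get(c, ""))
                       for c in score_cols]
            fh.write("\t".join(fields) + "\n")
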