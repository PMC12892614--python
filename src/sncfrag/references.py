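"""Parental RNA references for small-RNA annotation.

A *parental reference* is the mature sense sequence of a nuclear tRNA,
mitochondrial tRNA, rRNA, Y RNA or miRNA hairpin, carrying a class label and a
family label (the anticodon family for tRNAs, the parental gene name
otherwise).  Fragments of these parents are the tsRNA/rsRNA/ysRNA species the
rest of the package quantifies.

The module also provides a synthetic reference generator so the whole pipeline
can be exercised with known ground truth: random sequences with realistic
lengths and the field's family naming (48 nuclear anticodon families, 22
mitochondrial tRNAs, rRNA subunits, RNY genes), rejection-sampled so that no
parent is a substring of another.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_CLASSES = ("GtRNA", "MtRNA", "rRNA", "YRNA", "miRNA")

#: matrix-row prefix per reference class ("miRNA" families keep their own name)
CLASS_PREFIX = {"GtRNA": "GtsRNA-", "MtRNA": "MtsRNA-", "rRNA": "rsRNA-", "YRNA": "ysRNA-"}

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}

# the 22 tRNAs encoded on the human mitochondrial genome, named AA-anticodon
MITO_TRNA_FAMILIES = [
    "Phe-GAA", "Val-TAC", "Leu-TAA", "Ile-GAT", "Gln-TTG", "Met-CAT",
    "Trp-TCA", "Ala-TGC", "Asn-GTT", "Cys-GCA", "Tyr-GTA", "Ser-TGA",
    "Asp-GTC", "Lys-TTT", "Gly-TCC", "Arg-TCG", "His-GTG", "Ser-GCT",
    "Leu-TAG", "Glu-TTC", "Thr-TGT", "Pro-TGG",
]

RRNA_LABELS = ["12S", "16S", "5S", "5.8S", "18S", "28S", "45S", "ITS2"]


def _nuclear_trna_families() -> list[str]:
    """Anticodon family names (``Arg-ACG`` style) derived from the standard
    genetic code: one family per sense codon, ordered by amino acid then
    anticodon."""
    table = CodonTable.unambiguous_dna_by_id[1]
    fams = []
    for codon, aa in table.forward_table.items():
        anticodon = str(Seq(codon).reverse_complement())
        fams.append(f"{_AA3[aa]}-{anticodon}")
    return sorted(set(fams))


NUCLEAR_TRNA_FAMILIES = _nuclear_trna_families()


@dataclass(frozen=True)
class ParentalReference:
    """One mature parental RNA sequence.

    ``family`` is the aggregation unit used downstream: the anticodon family
    for tRNAs, the parental gene for rRNA/Y RNA, the miRNA name for miRNAs.
    """

    parent_id: str
    rna_class: str
    family: str
    sequence: str

    def __post_init__(self):
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}")
        if not self.sequence:
            raise ValueError(f"{self.parent_id}: empty sequence")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.parent_id}: sequence contains non-ACGT characters")

    @property
    def family_label(self) -> str:
        """Family label with class prefix, e.g. ``GtsRNA-Arg-ACG``."""
        return CLASS_PREFIX.get(self.rna_class, "") + self.family

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceConfig:
    """Composition of a synthetic reference set.

    Defaults mirror the category structure of human blood small-RNA profiling:
    48 nuclear anticodon families, 22 mitochondrial tRNAs, 8 rRNAs, 4 Y RNAs.
    """

    n_nuclear_trna_families: int = 48
    n_mito_trna_families: int = 22
    n_rrna: int = 8
    n_yrna: int = 4
    n_mirna: int = 50
    trna_length_range: tuple[int, int] = (70, 90)
    rrna_length_range: tuple[int, int] = (120, 400)
    yrna_length_range: tuple[int, int] = (83, 113)
    mirna_length_range: tuple[int, int] = (55, 85)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_nuclear_trna_families", "n_mito_trna_families",
                     "n_rrna", "n_yrna", "n_mirna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("trna_length_range", "rrna_length_range",
                     "yrna_length_range", "mirna_length_range"):
            lo, hi = getattr(self, name)
            if not (50 <= lo <= hi <= 2000):
                raise ValueError(f"{name} must lie within [50, 2000] nt")
        if self.n_nuclear_trna_families > len(NUCLEAR_TRNA_FAMILIES):
            raise ValueError(
                f"at most {len(NUCLEAR_TRNA_FAMILIES)} nuclear anticodon families available")
        if self.n_mito_trna_families > len(MITO_TRNA_FAMILIES):
            raise ValueError(f"at most {len(MITO_TRNA_FAMILIES)} mitochondrial tRNAs available")


def _rrna_labels(n: int) -> list[str]:
    labels = list(RRNA_LABELS)
    labels += [f"rX{i}" for i in range(1, max(0, n - len(labels)) + 1)]
    return labels[:n]


def _yrna_labels(n: int) -> list[str]:
    return [f"RNY{i}" for i in range(1, n + 1)]


_MAX_TRIES = 1000


def _sample_sequence(rng: np.random.Generator, length_range: tuple[int, int],
                     accepted: list[str], suffix: str = "", label: str = "") -> str:
    """Random ACGT sequence avoiding substring containment with already
    accepted parents (either direction), by rejection sampling."""
    lo, hi = length_range
    for _ in range(_MAX_TRIES):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
        if suffix:
            seq = seq[: n - len(suffix)] + suffix
        collision = next(
            (other for other in accepted if seq in other or other in seq), None)
        if collision is None:
            return seq
    raise RuntimeError(
        f"reference generation: could not place {label or 'sequence'} without "
        f"substring containment against an accepted parent "
        f"(last collision with a sequence of length {len(collision)}) "
        f"after {_MAX_TRIES} tries")


def generate_references(config: ReferenceConfig) -> list[ParentalReference]:
    """Generate a synthetic parental reference set.

    Nuclear tRNAs end in the mature ``CCA`` tail; families/labels follow the
    conventions above.  Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    refs: list[ParentalReference] = []
    accepted: list[str] = []

    def add(parent_id, rna_class, family, seq):
        refs.append(ParentalReference(parent_id, rna_class, family, seq))
        accepted.append(seq)

    for fam in NUCLEAR_TRNA_FAMILIES[: config.n_nuclear_trna_families]:
        seq = _sample_sequence(rng, config.trna_length_range, accepted,
                               suffix="CCA", label=f"GtRNA {fam}")
        add(f"GtRNA-{fam}", "GtRNA", fam, seq)
    for fam in MITO_TRNA_FAMILIES[: config.n_mito_trna_families]:
        seq = _sample_sequence(rng, config.trna_length_range, accepted,
                               label=f"MtRNA {fam}")
        add(f"MtRNA-{fam}", "MtRNA", fam, seq)
    for fam in _rrna_labels(config.n_rrna):
        seq = _sample_sequence(rng, config.rrna_length_range, accepted,
                               label=f"rRNA {fam}")
        add(f"rRNA-{fam}", "rRNA", fam, seq)
    for fam in _yrna_labels(config.n_yrna):
        seq = _sample_sequence(rng, config.yrna_length_range, accepted,
                               label=f"YRNA {fam}")
        add(f"YRNA-{fam}", "YRNA", fam, seq)
    for i in range(1, config.n_mirna + 1):
        fam = f"miR-{i:03d}"
        seq = _sample_sequence(rng, config.mirna_length_range, accepted,
                               label=f"miRNA {fam}")
        add(fam, "miRNA", fam, seq)
    return refs


def write_reference_fasta(refs: list[ParentalReference], path) -> None:
    """Write references with the ``>{class}|{parent_id}|{family}`` header."""
    records = [
        SeqRecord(Seq(r.sequence), id=f"{r.rna_class}|{r.parent_id}|{r.family}",
                  description="")
        for r in refs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_reference_fasta(path) -> list[ParentalReference]:
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"reference header {rec.id!r} does not follow 'class|parent_id|family'")
        rna_class, parent_id, fam = parts
        refs.append(ParentalReference(parent_id, rna_class, fam, str(rec.seq).upper()))
    return refs


def references_fasta_bytes(refs: list[ParentalReference]) -> bytes:
    buf = io.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=f"{r.rna_class}|{r.parent_id}|{r.family}",
                   description="") for r in refs],
        buf, "fasta")
    return buf.getvalue().encode()
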