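"""Reference gene architecture and translation utilities.

The central object is :class:`GeneModel`: an ordered list of coding exons
(by convention numbered 2..13 for ENaC-subunit genes, where exon 2 carries
the start codon and exon 13 the STOP) together with the expected splice
dinucleotides flanking each exon and, optionally, the reference intron
sequences separating them.  Exon sequences are coding sequence only; the
concatenation of all exons from the start exon is the reference CDS and
must form a continuous open reading frame ending in exactly one STOP.

Coordinates are 0-based half-open throughout the library; human-facing
reports convert to 1-based inclusive at the I/O layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio.Data import CodonTable

STOP_SYMBOL = "*"
_DNA = set("ACGT")
_DNA_N = set("ACGTN")

#: donor/acceptor dinucleotides accepted by the splicing machinery
CANONICAL_DONOR = "GT"
CANONICAL_ACCEPTOR = "AG"
TOLERATED_DONORS = frozenset({"GC"})
TOLERATED_ACCEPTORS = frozenset({"AC"})

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(_FORWARD))


class MalformedCdsError(ValueError):
    """Raised for empty or otherwise untranslatable coding sequence input."""


def translate(cds: str, phase: int = 0) -> str:
    """Translate ``cds`` starting at reading-frame offset ``phase``.

    Codons containing ``N`` translate to ``X`` (``X`` never counts as a
    STOP); STOP codons are rendered as ``*``; a trailing partial codon is
    dropped.  ``phase`` must be 0, 1 or 2 and simply skips that many
    leading bases.
    """
    if not cds:
        raise MalformedCdsError("empty coding sequence")
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase!r}")
    s = cds.upper()
    bad = set(s) - _DNA_N
    if bad:
        raise MalformedCdsError(f"non-ACGTN characters in CDS: {sorted(bad)}")
    out = []
    for i in range(phase, len(s) - 2, 3):
        codon = s[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append(STOP_SYMBOL)
        else:
            out.append(_FORWARD[codon])
    return "".join(out)


@dataclass(frozen=True)
class ExonDef:
    """One coding exon of the reference model.

    ``phase`` is the cumulative CDS length of all upstream exons modulo 3
    (i.e. the reading-frame offset at which this exon starts).
    ``expected_donor``/``expected_acceptor`` are the intronic dinucleotides
    immediately 3'/5' of the exon in the reference; ``None`` marks the
    terminal/first exon respectively.
    """

    number: int
    sequence: str
    phase: int
    expected_donor: Optional[str] = None
    expected_acceptor: Optional[str] = None


@dataclass(frozen=True)
class TargetLocus:
    """A genomic locus of one species in which the gene is searched."""

    species_id: str
    locus_id: str
    sequence: str
    orientation: str = "forward"  # forward | reverse, as resolved

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("locus sequence must be non-empty")


@dataclass(frozen=True)
class GeneModel:
    """Reference exon/intron architecture of one gene.

    ``introns``, when present, holds the reference intron sequences between
    consecutive exons (``len(introns) == len(exons) - 1``); the simulator
    uses them to emit full genomic loci.  The expected splice dinucleotides
    of each :class:`ExonDef` are consistent with the intron termini.
    """

    gene_id: str
    exons: tuple[ExonDef, ...]
    codon_table: int = 1
    start_exon: int = 0  # index into exons carrying the ATG
    stop_exon: int = -1  # index into exons carrying the STOP
    introns: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(self.exons))
        object.__setattr__(self, "introns", tuple(self.introns))
        if self.stop_exon == -1:
            object.__setattr__(self, "stop_exon", len(self.exons) - 1)

    @property
    def cds(self) -> str:
        """Reference coding sequence (exons concatenated from the start exon)."""
        return "".join(e.sequence for e in self.exons[self.start_exon :])

    def exon_by_number(self, number: int) -> ExonDef:
        for e in self.exons:
            if e.number == number:
                return e
        raise KeyError(f"no exon numbered {number} in {self.gene_id}")

    def exon_index(self, number: int) -> int:
        for i, e in enumerate(self.exons):
            if e.number == number:
                return i
        raise KeyError(f"no exon numbered {number} in {self.gene_id}")

    # ------------------------------------------------------------------ I/O
    def to_json(self, indent: int = 2) -> str:
        payload = {
            "gene_id": self.gene_id,
            "codon_table": self.codon_table,
            "start_exon": self.start_exon,
            "stop_exon": self.stop_exon,
            "exons": [
                {
                    "number": e.number,
                    "sequence": e.sequence,
                    "phase": e.phase,
                    "expected_donor": e.expected_donor,
                    "expected_acceptor": e.expected_acceptor,
                }
                for e in self.exons
            ],
            "introns": list(self.introns),
        }
        return json.dumps(payload, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "GeneModel":
        d = json.loads(text)
        exons = tuple(
            ExonDef(
                number=e["number"],
                sequence=e["sequence"],
                phase=e["phase"],
                expected_donor=e.get("expected_donor"),
                expected_acceptor=e.get("expected_acceptor"),
            )
            for e in d["exons"]
        )
        return cls(
            gene_id=d["gene_id"],
            exons=exons,
            codon_table=d.get("codon_table", 1),
            start_exon=d.get("start_exon", 0),
            stop_exon=d.get("stop_exon", len(exons) - 1),
            introns=tuple(d.get("introns", ())),
        )

    def to_fasta(self) -> str:
        """Exon sequences as multi-FASTA with ``gene|exon<N>`` headers."""
        recs = []
        for e in self.exons:
            recs.append(f">{self.gene_id}|exon{e.number}\n{e.sequence}")
        return "\n".join(recs) + "\n"


@dataclass(frozen=True)
class ModelViolation:
    """One invariant violation found by :func:`validate_model`."""

    kind: str  # phase_mismatch | internal_stop | missing_start | missing_stop |
    #            exon_order | bad_sequence | missing_splice_context
    location: str
    message: str


def validate_model(model: GeneModel) -> list[ModelViolation]:
    """Check every :class:`GeneModel` invariant; violations are data, not errors."""
    out: list[ModelViolation] = []
    numbers = [e.number for e in model.exons]
    if numbers != sorted(numbers) or len(set(numbers)) != len(numbers):
        out.append(
            ModelViolation("exon_order", model.gene_id, "exon numbers not strictly increasing")
        )
    cum = 0
    for e in model.exons:
        if set(e.sequence) - _DNA:
            out.append(
                ModelViolation(
                    "bad_sequence", f"exon{e.number}", "sequence not over {A,C,G,T}"
                )
            )
        if e.phase != cum % 3:
            out.append(
                ModelViolation(
                    "phase_mismatch",
                    f"exon{e.number}",
                    f"declared phase {e.phase}, cumulative length implies {cum % 3}",
                )
            )
        cum += len(e.sequence)
    n = len(model.exons)
    for i, e in enumerate(model.exons):
        if i < n - 1 and e.expected_donor is None:
            out.append(
                ModelViolation(
                    "missing_splice_context", f"exon{e.number}", "internal exon lacks donor"
                )
            )
        if i > 0 and e.expected_acceptor is None:
            out.append(
                ModelViolation(
                    "missing_splice_context", f"exon{e.number}", "internal exon lacks acceptor"
                )
            )
    cds = model.cds
    if len(cds) >= 3 and not out:
        if not cds.startswith("ATG"):
            out.append(ModelViolation("missing_start", "exon%d" % model.exons[model.start_exon].number,
                                      "CDS does not begin with ATG"))
        aa = translate(cds, 0)
        stops = [i for i, a in enumerate(aa) if a == STOP_SYMBOL]
        if not stops or stops[-1] != len(aa) - 1:
            out.append(ModelViolation("missing_stop", model.gene_id, "CDS does not end in a STOP"))
        internal = [i for i in stops if i != len(aa) - 1]
        for i in internal:
            # locate the exon containing this codon
            pos = i * 3
            cum2 = 0
            exon_no = model.exons[-1].number
            for e in model.exons[model.start_exon :]:
                if cum2 <= pos < cum2 + len(e.sequence):
                    exon_no = e.number
                    break
                cum2 += len(e.sequence)
            out.append(
                ModelViolation(
                    "internal_stop", f"exon{exon_no}", f"in-frame STOP at codon {i + 1}"
                )
            )
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")
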