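"""Synthetic gene loci evolved along a phylogeny with truth-logged lesions.

The simulator builds an ENaC-like multi-exon reference gene
(:func:`build_reference_model`), assembles it into a genomic locus
(flank + exon/intron alternation + flank) and evolves that locus along a
rooted tree (:func:`evolve_along_tree`).  Background change is neutral
Jukes-Cantor substitution plus short intronic indels; inactivating or
structural changes are *planted* as explicit :class:`PlantedEvent` objects
on named branches and inherited Dollo-style by every descendant.  A
:class:`SimTruth` log records, per tip, the realised events, the background
substitution count and the exact exon intervals, so every downstream stage
can be scored against known truth.

Truth is kept unambiguous by construction: background substitutions never
touch splice dinucleotides, the start/stop codons or planted-event
footprints, and proposals that would create an in-frame STOP in the current
coding frame are rejected (a functional gene under purifying selection does
not fix nonsense mutations; for planted pseudogenes the same rule simply
keeps background noise from mimicking planted lesions).  Coding indels only
ever enter as planted events; background indels are confined to introns and
flanks.  Planted splice mutations are additionally made "rescue-proof":
nearby frame-preserving canonical dinucleotides are scrubbed so that the
downstream classifier's rescue scan cannot silently neutralise a planted
lesion.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .gene_model import (
    ExonDef,
    GeneModel,
    STOP_CODONS,
    SENSE_CODONS,
    reverse_complement,
    translate,
    validate_model,
)
from . import treeutil

# ------------------------------------------------------------------ events

SPLICE_DONOR_MUT = "SPLICE_DONOR_MUT"
SPLICE_ACCEPTOR_MUT = "SPLICE_ACCEPTOR_MUT"
FRAMESHIFT_INDEL = "FRAMESHIFT_INDEL"
INFRAME_INDEL = "INFRAME_INDEL"
PREMATURE_STOP = "PREMATURE_STOP"
EXON_DELETION = "EXON_DELETION"
EXON_FUSION = "EXON_FUSION"

EVENT_KINDS = (
    SPLICE_DONOR_MUT,
    SPLICE_ACCEPTOR_MUT,
    FRAMESHIFT_INDEL,
    INFRAME_INDEL,
    PREMATURE_STOP,
    EXON_DELETION,
    EXON_FUSION,
)

#: event kinds that on their own make the gene a pseudogene
DISRUPTING_KINDS = frozenset(
    {SPLICE_DONOR_MUT, SPLICE_ACCEPTOR_MUT, FRAMESHIFT_INDEL, PREMATURE_STOP, EXON_DELETION}
)

_BASES = "ACGT"


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlantedEvent:
    """One lesion planted on a named branch and inherited by all descendants."""

    branch: str
    kind: str
    exon_number: int
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "kind": self.kind,
            "exon_number": self.exon_number,
            "detail": dict(self.detail),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedEvent":
        return cls(d["branch"], d["kind"], d["exon_number"], dict(d.get("detail", {})))


@dataclass
class TipTruth:
    species_id: str
    events: list[PlantedEvent]
    n_substitutions: int
    exon_intervals: dict[int, tuple[int, int]]  # forward-strand, 0-based half-open
    fused_introns: list[tuple[int, int, int]]  # (upstream exon, downstream exon, length)
    status: str  # INTACT | INTACT_FUSION | PSEUDOGENE
    reversed: bool = False


@dataclass
class SimTruth:
    seed: int
    tips: dict[str, TipTruth]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "tips": {
                sp: {
                    "events": [e.to_dict() for e in t.events],
                    "n_substitutions": t.n_substitutions,
                    "exon_intervals": {str(k): list(v) for k, v in t.exon_intervals.items()},
                    "fused_introns": [list(f) for f in t.fused_introns],
                    "status": t.status,
                    "reversed": t.reversed,
                }
                for sp, t in self.tips.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        tips = {}
        for sp, t in d["tips"].items():
            tips[sp] = TipTruth(
                species_id=sp,
                events=[PlantedEvent.from_dict(e) for e in t["events"]],
                n_substitutions=t["n_substitutions"],
                exon_intervals={int(k): tuple(v) for k, v in t["exon_intervals"].items()},
                fused_introns=[tuple(f) for f in t["fused_introns"]],
                status=t["status"],
                reversed=t.get("reversed", False),
            )
        return cls(seed=d["seed"], tips=tips)


# ------------------------------------------------------ reference building


def _random_sense_codons(n: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return "".join(SENSE_CODONS[i] for i in idx)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def build_reference_model(
    n_exons: int = 12,
    exon_length_range: tuple[int, int] = (80, 250),
    intron_length_range: tuple[int, int] = (150, 600),
    gc_donor_fraction: float = 0.0,
    seed: int = 0,
    first_exon_number: int = 2,
    gene_id: str = "GENE",
) -> GeneModel:
    """Generate a valid multi-exon reference gene model.

    The concatenated exon CDS starts with ATG, ends in a single STOP and is
    free of internal STOPs.  Splice donors are GT with probability
    ``1 - gc_donor_fraction``, else GC (the rare tolerated non-canonical
    donor); acceptors are AG.  Same seed, same model, byte for byte.
    """
    if n_exons < 2:
        raise SimulationError("need at least 2 exons")
    lo, hi = exon_length_range
    if lo < 3:
        raise SimulationError("exon lengths must be >= 3")
    ilo, ihi = intron_length_range
    if ilo < 6:
        raise SimulationError("intron lengths must be >= 6")
    rng = np.random.default_rng([int(seed), 17])
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_exons)]
    total = sum(lengths)
    lengths[-1] += (-total) % 3  # make CDS a codon multiple
    total = sum(lengths)
    cds = "ATG" + _random_sense_codons(total // 3 - 2, rng) + "TAA"
    exon_seqs = []
    pos = 0
    for L in lengths:
        exon_seqs.append(cds[pos : pos + L])
        pos += L
    introns = []
    for _ in range(n_exons - 1):
        L = int(rng.integers(ilo, ihi + 1))
        donor = "GC" if rng.random() < gc_donor_fraction else "GT"
        introns.append(donor + _random_dna(L - 4, rng) + "AG")
    exons = []
    cum = 0
    for i, s in enumerate(exon_seqs):
        exons.append(
            ExonDef(
                number=first_exon_number + i,
                sequence=s,
                phase=cum % 3,
                expected_donor=introns[i][:2] if i < n_exons - 1 else None,
                expected_acceptor=introns[i - 1][-2:] if i > 0 else None,
            )
        )
        cum += len(s)
    model = GeneModel(gene_id=gene_id, exons=tuple(exons), introns=tuple(introns))
    violations = validate_model(model)
    if violations:  # pragma: no cover - construction guarantees validity
        raise SimulationError(f"generated model invalid: {violations[:3]}")
    return model


# ------------------------------------------------------------- locus state


class _Segment:
    """Mutable piece of the evolving locus (flank, exon or intron)."""

    __slots__ = ("kind", "number", "seq", "mask", "fused")

    def __init__(self, kind: str, number: Optional[int], seq: str, mask=None, fused=False):
        self.kind = kind  # flank | exon | intron
        self.number = number  # exon number; for introns: upstream exon number
        self.seq = list(seq)
        self.mask = list(mask) if mask is not None else [False] * len(seq)
        self.fused = fused

    def copy(self) -> "_Segment":
        return _Segment(self.kind, self.number, "", None, self.fused)._steal(self)

    def _steal(self, other):
        self.seq = list(other.seq)
        self.mask = list(other.mask)
        return self

    @property
    def coding(self) -> bool:
        return self.kind == "exon" or (self.kind == "intron" and self.fused)

    def __len__(self):
        return len(self.seq)


def _root_segments(model: GeneModel, flank_length: int, rng: np.random.Generator):
    segs = [_Segment("flank", None, _random_dna(flank_length, rng))]
    n = len(model.exons)
    for i, e in enumerate(model.exons):
        seg = _Segment("exon", e.number, e.sequence)
        if i == model.start_exon:
            for p in range(3):  # protect ATG
                seg.mask[p] = True
        if i == model.stop_exon:
            for p in range(1, 4):  # protect terminal STOP
                seg.mask[-p] = True
        segs.append(seg)
        if i < n - 1:
            iseg = _Segment("intron", e.number, model.introns[i])
            iseg.mask[0] = iseg.mask[1] = True  # donor
            iseg.mask[-1] = iseg.mask[-2] = True  # acceptor
            segs.append(iseg)
    segs.append(_Segment("flank", None, _random_dna(flank_length, rng)))
    return segs


def _coding_positions(segs) -> list[tuple[int, int]]:
    """(segment index, offset) of every coding base, in CDS order."""
    out = []
    for si, seg in enumerate(segs):
        if seg.coding:
            out.extend((si, p) for p in range(len(seg)))
    return out


def _codon_is_stop(segs, cds_positions, ci: int) -> bool:
    start = 3 * ci
    if start + 3 > len(cds_positions):
        return False
    codon = "".join(segs[si].seq[p] for si, p in cds_positions[start : start + 3])
    return codon in STOP_CODONS


def _cds_index_map(cds_positions) -> dict[tuple[int, int], int]:
    return {sp: i for i, sp in enumerate(cds_positions)}


# ----------------------------------------------------- background processes


def _apply_substitutions(segs, rate: float, blen: float, rng: np.random.Generator) -> int:
    free = [
        (si, p)
        for si, seg in enumerate(segs)
        for p in range(len(seg))
        if not seg.mask[p]
    ]
    if not free or rate <= 0 or blen <= 0:
        return 0
    count = int(rng.poisson(rate * blen * len(free)))
    if count == 0:
        return 0
    cds_positions = _coding_positions(segs)
    cds_index = _cds_index_map(cds_positions)
    applied = 0
    attempts = 0
    while applied < count and attempts < 50 * count + 100:
        attempts += 1
        si, p = free[int(rng.integers(0, len(free)))]
        seg = segs[si]
        old = seg.seq[p]
        alts = [b for b in _BASES if b != old]
        new = alts[int(rng.integers(0, 3))]
        if seg.coding:
            ci = cds_index[(si, p)] // 3
            seg.seq[p] = new
            if _codon_is_stop(segs, cds_positions, ci):
                seg.seq[p] = old  # would create a nonsense codon; redraw
                continue
            applied += 1
        else:
            seg.seq[p] = new
            applied += 1
    return applied


def _apply_background_indels(segs, rate: float, blen: float, rng: np.random.Generator):
    # background indels live in non-fused introns and flanks only
    eligible = [
        si
        for si, seg in enumerate(segs)
        if (seg.kind == "flank" or (seg.kind == "intron" and not seg.fused)) and len(seg) > 30
    ]
    if not eligible or rate <= 0 or blen <= 0:
        return
    total_len = sum(len(segs[si]) for si in eligible)
    count = int(rng.poisson(rate * blen * total_len))
    for _ in range(count):
        weights = np.array([len(segs[si]) for si in eligible], dtype=float)
        si = eligible[int(rng.choice(len(eligible), p=weights / weights.sum()))]
        seg = segs[si]
        L = min(10, 1 + int(rng.geometric(0.5)))
        interior_lo, interior_hi = 4, len(seg) - 4  # keep splice context intact
        if interior_hi - interior_lo < L + 2:
            continue
        off = int(rng.integers(interior_lo, interior_hi - L))
        if rng.random() < 0.5:  # insertion
            ins = _random_dna(L, rng)
            seg.seq[off:off] = list(ins)
            seg.mask[off:off] = [False] * L
        else:  # deletion
            del seg.seq[off : off + L]
            del seg.mask[off : off + L]


# --------------------------------------------------------- event application


def _find_exon(segs, number: int) -> int:
    for si, seg in enumerate(segs):
        if seg.kind == "exon" and seg.number == number:
            return si
    raise SimulationError(f"event references exon {number}, which was deleted upstream")


def _find_intron_after(segs, exon_number: int) -> int:
    for si, seg in enumerate(segs):
        if seg.kind == "intron" and seg.number == exon_number:
            return si
    raise SimulationError(f"no intron after exon {exon_number} (deleted or terminal)")


def _coding_len_before(segs, si: int) -> int:
    return sum(len(s) for s in segs[:si] if s.coding)


def _scrub_donor_rescues(segs, intron_si: int, window: int = 45):
    """Remove frame-preserving GT donors near a mutated donor boundary."""
    intron = segs[intron_si]
    exon = segs[intron_si - 1]
    for delta in range(3, window + 1, 3):
        # candidate donor inside the intron at offset delta
        if delta + 2 <= len(intron) - 2:
            if intron.seq[delta] == "G" and intron.seq[delta + 1] == "T":
                intron.seq[delta + 1] = "C"  # GT -> GC: tolerated, not a rescue
    for delta in range(-3, -window - 1, -3):
        q = len(exon) + delta
        if 0 <= q < len(exon) - 1:
            if exon.seq[q] == "G" and exon.seq[q + 1] == "T" and not exon.mask[q + 1]:
                exon.seq[q + 1] = "C"  # C in a codon can never form a STOP


def _scrub_acceptor_rescues(segs, intron_si: int, window: int = 45):
    intron = segs[intron_si]
    exon = segs[intron_si + 1]
    for delta in range(-3, -window - 1, -3):
        q = len(intron) + delta - 2
        if 2 <= q < len(intron) - 2:
            if intron.seq[q] == "A" and intron.seq[q + 1] == "G":
                intron.seq[q + 1] = "C"  # AG -> AC: tolerated, not a rescue
    for delta in range(3, window + 1, 3):
        q = delta - 2
        if 0 <= q < len(exon) - 1:
            if exon.seq[q] == "A" and exon.seq[q + 1] == "G" and not exon.mask[q + 1]:
                exon.seq[q + 1] = "C"


def _ensure_readthrough_stop(segs, intron_si: int):
    """A mutated (non-fusion) donor must not read through cleanly in frame."""
    intron = segs[intron_si]
    if len(intron) % 3 != 0:
        return
    frame_start = _coding_len_before(segs, intron_si)
    # absolute coding-style offset of the intron start within the fused reading
    off = (-frame_start) % 3
    for p in range(off, len(intron) - 2, 3):
        codon = "".join(intron.seq[p : p + 3])
        if codon in STOP_CODONS:
            return
    # no in-frame stop by chance: plant one mid-intron
    p = off + 3 * ((len(intron) // 2) // 3)
    p = min(max(p, 3), len(intron) - 6)
    p = p - ((p - off) % 3)
    intron.seq[p : p + 3] = list("TAA")


def _apply_event(segs, ev: PlantedEvent):
    d = ev.detail
    if ev.kind == SPLICE_DONOR_MUT:
        si = _find_intron_after(segs, ev.exon_number)
        to = d.get("to", "AT")
        segs[si].seq[0:2] = list(to)
        segs[si].mask[0] = segs[si].mask[1] = True
        _scrub_donor_rescues(segs, si)
        _ensure_readthrough_stop(segs, si)
    elif ev.kind == SPLICE_ACCEPTOR_MUT:
        ei = _find_exon(segs, ev.exon_number)
        if ei == 0 or segs[ei - 1].kind != "intron":
            raise SimulationError(f"exon {ev.exon_number} has no upstream intron")
        si = ei - 1
        to = d.get("to", "GG")
        segs[si].seq[-2:] = list(to)
        segs[si].mask[-1] = segs[si].mask[-2] = True
        _scrub_acceptor_rescues(segs, si)
    elif ev.kind in (FRAMESHIFT_INDEL, INFRAME_INDEL):
        ei = _find_exon(segs, ev.exon_number)
        seg = segs[ei]
        off = int(d["offset"])
        if d["op"] == "ins":
            ins = d["seq"]
            if ev.kind == FRAMESHIFT_INDEL and len(ins) % 3 == 0:
                raise SimulationError("frameshift insertion length must not be a codon multiple")
            if ev.kind == INFRAME_INDEL and len(ins) % 3 != 0:
                raise SimulationError("in-frame insertion length must be a codon multiple")
            seg.seq[off:off] = list(ins)
            seg.mask[off:off] = [True] * len(ins)
        else:
            L = int(d["length"])
            if ev.kind == FRAMESHIFT_INDEL and L % 3 == 0:
                raise SimulationError("frameshift deletion length must not be a codon multiple")
            if ev.kind == INFRAME_INDEL and L % 3 != 0:
                raise SimulationError("in-frame deletion length must be a codon multiple")
            if off + L > len(seg):
                raise SimulationError("deletion exceeds exon bounds")
            del seg.seq[off : off + L]
            del seg.mask[off : off + L]
            # protect the junction so later background noise keeps truth clean
            for p in range(max(0, off - 2), min(len(seg), off + 2)):
                seg.mask[p] = True
    elif ev.kind == PREMATURE_STOP:
        ei = _find_exon(segs, ev.exon_number)
        seg = segs[ei]
        off = int(d["offset"])
        codon = d.get("codon", "TAA")
        if off + 3 > len(seg):
            raise SimulationError("premature stop offset out of exon bounds")
        seg.seq[off : off + 3] = list(codon)
        for p in range(off, off + 3):
            seg.mask[p] = True
    elif ev.kind == EXON_DELETION:
        ei = _find_exon(segs, ev.exon_number)
        # remove the exon and the intron that follows it (or precedes, if terminal)
        if ei + 1 < len(segs) and segs[ei + 1].kind == "intron":
            del segs[ei : ei + 2]
        elif segs[ei - 1].kind == "intron":
            del segs[ei - 1 : ei + 1]
        else:  # pragma: no cover
            del segs[ei]
    elif ev.kind == EXON_FUSION:
        si = _find_intron_after(segs, ev.exon_number)
        seq = d["sequence"]
        if len(seq) % 3 != 0:
            raise SimulationError("fusion intron length must be a codon multiple")
        seg = segs[si]
        seg.seq = list(seq)
        seg.mask = [False] * len(seq)
        seg.mask[0] = seg.mask[1] = True
        seg.mask[-1] = seg.mask[-2] = True
        seg.fused = True
        _fix_fusion_junction_stops(segs, si)
    else:
        raise SimulationError(f"unknown event kind {ev.kind!r}")


def _fix_fusion_junction_stops(segs, si: int):
    """No STOP may overlap the fused intron in any frame (read-through safety)."""
    intron = segs[si]
    left = segs[si - 1]
    right = segs[si + 1]
    ctx = left.seq[-2:] + intron.seq + right.seq[:2]
    base_off = len(left.seq[-2:])
    changed = True
    guard = 0
    while changed and guard < 50:
        changed = False
        guard += 1
        for p in range(0, len(ctx) - 2):
            codon = "".join(ctx[p : p + 3])
            if codon in STOP_CODONS:
                # at least one base of the codon is intronic; neutralise it with C
                for q in range(p, p + 3):
                    ip = q - base_off
                    if 2 <= ip < len(intron) - 2:
                        intron.seq[ip] = "C"
                        ctx[q] = "C"
                        changed = True
                        break
                if changed:
                    break


# ------------------------------------------------------------- event makers


def make_donor_mut(branch: str, exon: int, to: str = "AT") -> PlantedEvent:
    return PlantedEvent(branch, SPLICE_DONOR_MUT, exon, {"to": to})


def make_acceptor_mut(branch: str, exon: int, to: str = "GG") -> PlantedEvent:
    return PlantedEvent(branch, SPLICE_ACCEPTOR_MUT, exon, {"to": to})


def make_frameshift(
    branch: str, exon: int, offset: int, length: int, insert: bool, rng: np.random.Generator
) -> PlantedEvent:
    if length % 3 == 0:
        raise ValueError("frameshift length must not be a multiple of 3")
    if insert:
        return PlantedEvent(
            branch, FRAMESHIFT_INDEL, exon, {"op": "ins", "offset": offset, "seq": _random_dna(length, rng)}
        )
    return PlantedEvent(branch, FRAMESHIFT_INDEL, exon, {"op": "del", "offset": offset, "length": length})


def make_inframe_indel(
    model: GeneModel, branch: str, exon: int, offset: int, length: int, insert: bool,
    rng: np.random.Generator,
) -> PlantedEvent:
    """In-frame indel whose junction/insert introduces no in-frame STOP."""
    if length % 3 != 0:
        raise ValueError("in-frame indel length must be a multiple of 3")
    edef = model.exon_by_number(exon)
    phase = edef.phase
    for _ in range(200):
        if insert:
            ins = _random_dna(length, rng)
            new = edef.sequence[:offset] + ins + edef.sequence[offset:]
        else:
            new = edef.sequence[:offset] + edef.sequence[offset + length :]
        # prepend `phase` Ns so codon boundaries fall where the gene frame puts them
        aa = translate("N" * phase + new, 0) if phase else translate(new, 0)
        if "*" not in aa:
            if insert:
                return PlantedEvent(
                    branch, INFRAME_INDEL, exon, {"op": "ins", "offset": offset, "seq": ins}
                )
            return PlantedEvent(
                branch, INFRAME_INDEL, exon, {"op": "del", "offset": offset, "length": length}
            )
        if not insert:
            raise ValueError("in-frame deletion at this offset forms a junction STOP")
    raise ValueError("could not draw a STOP-free in-frame insertion")


def make_premature_stop(
    model: GeneModel, branch: str, exon: int, codon_index: int, codon: str = "TAA"
) -> PlantedEvent:
    """Replace the ``codon_index``-th full codon of the exon with a STOP."""
    edef = model.exon_by_number(exon)
    off = ((3 - edef.phase) % 3) + 3 * codon_index
    if off + 3 > len(edef.sequence):
        raise ValueError("codon index beyond exon")
    return PlantedEvent(branch, PREMATURE_STOP, exon, {"offset": off, "codon": codon})


def make_exon_deletion(branch: str, exon: int) -> PlantedEvent:
    return PlantedEvent(branch, EXON_DELETION, exon, {})


def make_exon_fusion(
    model: GeneModel,
    branch: str,
    exon: int,
    intron_length: int = 99,
    donor: str = "AT",
    rng: Optional[np.random.Generator] = None,
) -> PlantedEvent:
    """Replace the intron after ``exon`` with a clean in-frame retained intron.

    The replacement starts with a non-functional donor, ends with the intact
    AG acceptor, has length = 0 (mod 3) and carries no STOP in any reading
    frame (including codons spanning the exon/intron junctions), so that
    splicing loss yields an undisrupted "super exon".
    """
    if intron_length % 3 != 0:
        raise ValueError("fusion intron length must be a multiple of 3")
    if intron_length < 9:
        raise ValueError("fusion intron too short")
    rng = rng if rng is not None else np.random.default_rng(0)
    i = model.exon_index(exon)
    if i >= len(model.exons) - 1:
        raise ValueError("terminal exon has no downstream intron")
    left = model.exons[i].sequence[-2:]
    right = model.exons[i + 1].sequence[:2]
    for _ in range(500):
        interior = _random_sense_codons(intron_length // 3, rng)[: intron_length - 4]
        seq = donor + interior + "AG"
        ctx = left + seq + right
        if not any(ctx[p : p + 3] in STOP_CODONS for p in range(len(ctx) - 2)):
            return PlantedEvent(branch, EXON_FUSION, exon, {"sequence": seq})
    raise ValueError("could not draw a STOP-free fusion intron")


# ------------------------------------------------------------ tree evolution


def evolve_along_tree(
    model: GeneModel,
    tree,
    sub_rate: float,
    indel_rate: float,
    planted: Sequence[PlantedEvent],
    seed: int,
    flank_length: int = 100,
    reverse_tips: Iterable[str] = (),
):
    """Evolve the reference locus along ``tree``; return (loci, truth).

    Substitution and indel counts on each branch are Poisson with mean
    rate x branch length x eligible sites.  Planted events are applied on
    their branch *after* that branch's background changes and are inherited
    by every descendant.  Per-branch random streams are split from the
    master seed, so adding a planted event never changes background noise
    elsewhere.
    """
    if sub_rate < 0 or indel_rate < 0:
        raise ValueError("rates must be >= 0")
    tree = treeutil.load_tree(tree)
    branch_index = {
        treeutil.branch_id(nd): i for i, nd in enumerate(treeutil.branch_nodes(tree))
    }
    by_branch: dict[str, list[PlantedEvent]] = {}
    for ev in planted:
        if ev.branch not in branch_index:
            raise SimulationError(f"planted event references unknown branch {ev.branch!r}")
        by_branch.setdefault(ev.branch, []).append(ev)

    reverse_tips = set(reverse_tips)
    root_rng = np.random.default_rng([int(seed), 0])
    root_segs = _root_segments(model, flank_length, root_rng)

    loci: list = []
    tips: dict[str, TipTruth] = {}

    def recurse(node, segs, inherited: list[PlantedEvent], n_subs: int):
        for child in node.child_nodes():
            bid = treeutil.branch_id(child)
            blen = child.edge.length if child.edge.length is not None else 1.0
            rng = np.random.default_rng([int(seed), 1000 + branch_index[bid]])
            csegs = [s.copy() for s in segs]
            applied = _apply_substitutions(csegs, sub_rate, blen, rng)
            _apply_background_indels(csegs, indel_rate, blen, rng)
            cev = list(inherited)
            for ev in by_branch.get(bid, []):
                _apply_event(csegs, ev)
                cev.append(ev)
            if child.is_leaf():
                _finish_tip(child.taxon.label, csegs, cev, n_subs + applied)
            else:
                recurse(child, csegs, cev, n_subs + applied)

    def _finish_tip(sp: str, segs, events: list[PlantedEvent], n_subs: int):
        seq = "".join("".join(s.seq) for s in segs)
        intervals: dict[int, tuple[int, int]] = {}
        fused: list[tuple[int, int, int]] = []
        pos = 0
        for si, s in enumerate(segs):
            if s.kind == "exon":
                intervals[s.number] = (pos, pos + len(s))
            elif s.kind == "intron" and s.fused:
                nxt = segs[si + 1].number if si + 1 < len(segs) else None
                fused.append((s.number, nxt, len(s)))
            pos += len(s)
        kinds = {e.kind for e in events}
        if kinds & DISRUPTING_KINDS:
            status = "PSEUDOGENE"
        elif EXON_FUSION in kinds:
            status = "INTACT_FUSION"
        else:
            status = "INTACT"
        rev = sp in reverse_tips
        from .gene_model import TargetLocus

        loci.append(
            TargetLocus(
                species_id=sp,
                locus_id=f"{sp}_{model.gene_id}",
                sequence=reverse_complement(seq) if rev else seq,
            )
        )
        tips[sp] = TipTruth(
            species_id=sp,
            events=events,
            n_substitutions=n_subs,
            exon_intervals=intervals,
            fused_introns=fused,
            status=status,
            reversed=rev,
        )

    recurse(tree.seed_node, root_segs, [], 0)
    return loci, SimTruth(seed=int(seed), tips=tips)


# ----------------------------------------------------------------- fixtures


def write_fixture(loci, truth: SimTruth, out_dir, config: Optional[dict] = None):
    """Write one FASTA per species, a truth JSON and (optionally) the config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for locus in loci:
        path = out / f"{locus.species_id}.fasta"
        with open(path, "w") as fh:
            fh.write(f">{locus.locus_id}\n")
            for i in range(0, len(locus.sequence), 70):
                fh.write(locus.sequence[i : i + 70] + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
    if config is not None:
        with open(out / "config.json", "w") as fh:
            json.dump(config, fh, indent=2, sort_keys=True)


def read_fixture(out_dir):
    """Read back a fixture directory; returns (loci, truth)."""
    from .gene_model import TargetLocus

    out = Path(out_dir)
    with open(out / "truth.json") as fh:
        truth = SimTruth.from_dict(json.load(fh))
    loci = []
    for sp in sorted(truth.tips):
        lines = (out / f"{sp}.fasta").read_text().splitlines()
        header = lines[0][1:]
        seq = "".join(lines[1:])
        loci.append(TargetLocus(species_id=sp, locus_id=header, sequence=seq))
    return loci, truth


# --------------------------------------------------------- random scenarios


def make_random_tree(n_tips: int, rng: np.random.Generator, prefix: str = "sp"):
    """Random rooted binary tree over ``n_tips`` labelled tips (newick string)."""
    nodes = [f"{prefix}{i + 1:02d}:{rng.uniform(0.4, 1.2):.3f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        if len(nodes) == 0:
            nodes.append(f"({a},{b});")
        else:
            nodes.append(f"({a},{b}):{rng.uniform(0.3, 1.0):.3f}")
    return nodes[0]


@dataclass
class Scenario:
    """Everything needed to regenerate a simulated dataset byte-identically."""

    model_params: dict
    tree_newick: str
    sub_rate: float
    indel_rate: float
    planted: list[PlantedEvent]
    seed: int
    reverse_tips: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model_params": self.model_params,
            "tree_newick": self.tree_newick,
            "sub_rate": self.sub_rate,
            "indel_rate": self.indel_rate,
            "planted": [e.to_dict() for e in self.planted],
            "seed": self.seed,
            "reverse_tips": list(self.reverse_tips),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            model_params=dict(d["model_params"]),
            tree_newick=d["tree_newick"],
            sub_rate=d["sub_rate"],
            indel_rate=d["indel_rate"],
            planted=[PlantedEvent.from_dict(e) for e in d["planted"]],
            seed=d["seed"],
            reverse_tips=list(d.get("reverse_tips", [])),
        )


def run_scenario(scenario: Scenario):
    """Regenerate (model, loci, truth) from a scenario description."""
    model = build_reference_model(**scenario.model_params, seed=scenario.seed)
    loci, truth = evolve_along_tree(
        model,
        scenario.tree_newick,
        sub_rate=scenario.sub_rate,
        indel_rate=scenario.indel_rate,
        planted=scenario.planted,
        seed=scenario.seed,
        reverse_tips=scenario.reverse_tips,
    )
    return model, loci, truth


def _frame_disrupting(ev: PlantedEvent, model: GeneModel) -> bool:
    if ev.kind == FRAMESHIFT_INDEL:
        return True
    if ev.kind == EXON_DELETION:
        return True  # conservative: treat every exon loss as frame-relevant
    return False


def _intron_of(ev: PlantedEvent, model: GeneModel) -> Optional[int]:
    """Upstream-exon number of the intron an event touches, if any."""
    if ev.kind in (SPLICE_DONOR_MUT, EXON_FUSION):
        return ev.exon_number
    if ev.kind == SPLICE_ACCEPTOR_MUT:
        i = model.exon_index(ev.exon_number)
        return model.exons[i - 1].number if i > 0 else None
    return None


def random_scenario(
    n_tips: int,
    seed: int,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    n_events: int = 5,
    model_params: Optional[dict] = None,
    kind_cycle: Optional[list[str]] = None,
) -> Scenario:
    """Draw a random tree plus a set of mutually attributable planted events.

    Events are planted so each remains individually recoverable: at most one
    event per exon per lineage, one event per intron per lineage, and no
    premature STOP downstream (in gene order) of a frame-disrupting event on
    the same lineage (a shifted frame hides a reference-frame STOP codon).
    """
    rng = np.random.default_rng([int(seed), 7])
    params = dict(model_params or {})
    params.setdefault("n_exons", 12)
    model = build_reference_model(**params, seed=seed)
    newick = make_random_tree(n_tips, rng)
    tree = treeutil.load_tree(newick)
    branches = [treeutil.branch_id(nd) for nd in treeutil.branch_nodes(tree)]
    tips_below = {
        treeutil.branch_id(nd): frozenset(treeutil.leaves_under(nd))
        for nd in treeutil.branch_nodes(tree)
    }
    numbers = [e.number for e in model.exons]
    first, last = numbers[0], numbers[-1]
    kinds = list(kind_cycle) if kind_cycle else list(EVENT_KINDS)
    accepted: list[PlantedEvent] = []
    ki = int(rng.integers(0, len(kinds)))  # scenario-specific phase: all kinds get coverage
    attempts = 0
    while len(accepted) < n_events and attempts < 400:
        attempts += 1
        kind = kinds[ki % len(kinds)]
        branch = branches[int(rng.integers(0, len(branches)))]
        if kind in (SPLICE_DONOR_MUT, EXON_FUSION):
            exon = int(rng.choice(numbers[:-1]))
        elif kind == SPLICE_ACCEPTOR_MUT:
            exon = int(rng.choice(numbers[1:]))
        elif kind == EXON_DELETION:
            exon = int(rng.choice(numbers[1:-1]))
        else:
            exon = int(rng.choice(numbers))
        edef = model.exon_by_number(exon)
        try:
            if kind == SPLICE_DONOR_MUT:
                ev = make_donor_mut(branch, exon)
            elif kind == SPLICE_ACCEPTOR_MUT:
                ev = make_acceptor_mut(branch, exon)
            elif kind == EXON_FUSION:
                ev = make_exon_fusion(model, branch, exon, intron_length=99, rng=rng)
            elif kind == EXON_DELETION:
                ev = make_exon_deletion(branch, exon)
            elif kind == PREMATURE_STOP:
                n_codons = (len(edef.sequence) - ((3 - edef.phase) % 3)) // 3
                hi = n_codons - 1
                if exon == last:
                    hi = min(hi, n_codons - 12)  # stay out of the terminal STOP window
                if exon == first:
                    lo = 2
                else:
                    lo = 1
                if hi <= lo:
                    continue
                ev = make_premature_stop(model, branch, exon, int(rng.integers(lo, hi)))
            else:  # indels, kept clear of exon edges so placement stays unambiguous
                L = int(rng.choice([1, 2, 4, 5])) if kind == FRAMESHIFT_INDEL else int(rng.choice([3, 6]))
                if len(edef.sequence) < L + 26:
                    continue
                off = int(rng.integers(12, len(edef.sequence) - L - 12))
                insert = bool(rng.random() < 0.5)
                if kind == FRAMESHIFT_INDEL:
                    ev = make_frameshift(branch, exon, off, L, insert, rng)
                else:
                    ev = make_inframe_indel(model, branch, exon, off, L, insert, rng)
        except ValueError:
            continue
        # compatibility with already-accepted events sharing descendants
        ok = True
        for prev in accepted:
            if not (tips_below[prev.branch] & tips_below[ev.branch]):
                continue
            if prev.exon_number == ev.exon_number:
                ok = False
                break
            pi, ei = _intron_of(prev, model), _intron_of(ev, model)
            if pi is not None and pi == ei:
                ok = False
                break
            for a, b in ((prev, ev), (ev, prev)):
                if a.kind == EXON_DELETION:
                    # deletion of exon k removes intron k and re-joins intron k-1
                    idx = model.exon_index(a.exon_number)
                    touched = {a.exon_number}
                    bi = _intron_of(b, model)
                    if bi is not None and bi in (
                        a.exon_number,
                        model.exons[idx - 1].number if idx > 0 else None,
                    ):
                        ok = False
                # a shifted frame hides reference-frame STOPs and fusion read-through
                if _frame_disrupting(a, model) and b.kind in (PREMATURE_STOP, EXON_FUSION):
                    if b.exon_number > a.exon_number:
                        ok = False
            if not ok:
                break
        if ok:
            accepted.append(ev)
            ki += 1
    return Scenario(
        model_params=params,
        tree_newick=newick,
        sub_rate=sub_rate,
        indel_rate=indel_rate,
        planted=accepted,
        seed=int(seed),
    )


# ----------------------------------------------- codon-alignment simulation


def simulate_codon_alignment(
    tree,
    n_codons: int,
    rate: float,
    seed: int,
    foreground: Iterable[str] = (),
    omega_foreground: float = 1.0,
    omega_background: float = 1.0,
):
    """Neutral-or-thinned codon evolution for calibrating the selection screen.

    Single-nucleotide proposals arise uniformly (Jukes-Cantor) at Poisson
    rate ``rate`` per site per unit branch length; proposals creating a STOP
    are discarded, and nonsynonymous proposals are accepted with probability
    omega of the branch's partition (synonymous proposals always fix).  With
    omega = 1 everywhere this is neutral evolution over sense codons.

    Returns (alignment dict tip -> CDS string, dendropy tree).
    """
    tree = treeutil.load_tree(tree)
    rng = np.random.default_rng([int(seed), 3])
    root = _random_sense_codons(n_codons, rng)
    fg_edges: set[str] = set()
    foreground = list(foreground)
    if foreground:
        node = treeutil.mrca(tree, foreground)
        fg_edges = {treeutil.branch_id(nd) for nd in node.preorder_iter()}
    branch_index = {
        treeutil.branch_id(nd): i for i, nd in enumerate(treeutil.branch_nodes(tree))
    }
    out: dict[str, str] = {}

    def step(node, seq: list[str]):
        for child in node.child_nodes():
            bid = treeutil.branch_id(child)
            blen = child.edge.length if child.edge.length is not None else 1.0
            brng = np.random.default_rng([int(seed), 5000 + branch_index[bid]])
            omega = omega_foreground if bid in fg_edges else omega_background
            cseq = list(seq)
            n = int(brng.poisson(rate * blen * 3 * n_codons))
            for _ in range(n):
                p = int(brng.integers(0, 3 * n_codons))
                old = cseq[p]
                new = _BASES[int(brng.integers(0, 4))]
                if new == old:
                    continue
                ci = p // 3
                codon = cseq[3 * ci : 3 * ci + 3]
                newcodon = list(codon)
                newcodon[p % 3] = new
                nc = "".join(newcodon)
                if nc in STOP_CODONS:
                    continue
                syn = translate(nc) == translate("".join(codon))
                if not syn and brng.random() > omega:
                    continue
                cseq[p] = new
            if child.is_leaf():
                out[child.taxon.label] = "".join(cseq)
            else:
                step(child, cseq)

    step(tree.seed_node, list(root))
    return out, tree
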