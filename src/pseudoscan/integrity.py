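"""Lesion classification, exon-fusion detection and the per-gene verdict.

Exon hits are turned into :class:`Lesion` records (splice-site mutations,
frameshifting and in-frame indels, premature STOPs, missing exons), in-frame
"super exon" fusions are detected and reconciled against splice lesions, the
predicted CDS is assembled, and the gene is classified as INTACT,
INTACT_FUSION (fusion present, ORF undisrupted), PSEUDOGENE or INCOMPLETE
(assembly gaps prevent a call).

Two conventions matter downstream:

* A premature STOP that only exists because an upstream frameshift (or the
  junction of an indel) changed the reading frame is flagged
  ``secondary=True``: it is a consequence of that lesion, not an independent
  mutation, and is excluded from shared-lesion signatures and recovery
  scoring.
* A splice mutation neutralised by a fusion or by a frame-preserving rescue
  splice site is downgraded to non-disrupting but kept in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .gene_model import (
    CANONICAL_ACCEPTOR,
    CANONICAL_DONOR,
    GeneModel,
    STOP_CODONS,
    TOLERATED_ACCEPTORS,
    TOLERATED_DONORS,
    TargetLocus,
    translate,
)
from .mapping import ExonHit, ScoreParams, locate_exons, orient_locus

CANONICAL = "CANONICAL"
NONCANONICAL_TOLERATED = "NONCANONICAL_TOLERATED"
MUTATED = "MUTATED"

SPLICE_DONOR_MUT = "SPLICE_DONOR_MUT"
SPLICE_ACCEPTOR_MUT = "SPLICE_ACCEPTOR_MUT"
FRAMESHIFT_INDEL = "FRAMESHIFT_INDEL"
INFRAME_INDEL = "INFRAME_INDEL"
PREMATURE_STOP = "PREMATURE_STOP"
EXON_MISSING = "EXON_MISSING"


class AssemblyError(RuntimeError):
    pass


@dataclass(frozen=True)
class SpliceCall:
    category: str  # CANONICAL | NONCANONICAL_TOLERATED | MUTATED
    low_confidence: bool = False


def classify_splice_site(dinucleotide: str, side: str) -> SpliceCall:
    """Classify a splice dinucleotide: GT/AG canonical, GC/AC tolerated, else mutated."""
    if side not in ("donor", "acceptor"):
        raise ValueError(f"side must be 'donor' or 'acceptor', got {side!r}")
    if dinucleotide is None or len(dinucleotide) != 2:
        raise ValueError(f"splice site must be a 2-mer, got {dinucleotide!r}")
    d = dinucleotide.upper()
    if set(d) - set("ACGTN"):
        raise ValueError(f"splice 2-mer over ACGTN required, got {dinucleotide!r}")
    if "N" in d:
        return SpliceCall(MUTATED, low_confidence=True)
    if side == "donor":
        if d == CANONICAL_DONOR:
            return SpliceCall(CANONICAL)
        if d in TOLERATED_DONORS:
            return SpliceCall(NONCANONICAL_TOLERATED)
    else:
        if d == CANONICAL_ACCEPTOR:
            return SpliceCall(CANONICAL)
        if d in TOLERATED_ACCEPTORS:
            return SpliceCall(NONCANONICAL_TOLERATED)
    return SpliceCall(MUTATED)


@dataclass
class Lesion:
    """One inactivating or structural alteration of the gene."""

    kind: str
    exon_number: int
    offset: Optional[int] = None  # 0-based within the exon's target slice
    boundary: Optional[str] = None  # donor | acceptor, for splice lesions
    observed: str = ""
    reference: str = ""
    disrupting: bool = True
    secondary: bool = False  # consequence of an upstream frame change
    note: str = ""


@dataclass(frozen=True)
class FusionCall:
    """In-frame retention of the intron between two exons (a "super exon")."""

    upstream_exon: int
    downstream_exon: int
    intron_length: int
    incorporated_residues: int
    in_frame: bool = True


@dataclass
class GeneVerdict:
    """Per species x gene status: the cell of a presence/absence matrix."""

    species_id: str
    gene_id: str
    status: str  # INTACT | INTACT_FUSION | PSEUDOGENE | INCOMPLETE
    lesions: list[Lesion] = field(default_factory=list)
    fusions: list[FusionCall] = field(default_factory=list)
    cds: Optional[str] = None
    confidence: list[str] = field(default_factory=list)
    hits: list[ExonHit] = field(default_factory=list)

    @property
    def disrupting_lesions(self) -> list[Lesion]:
        return [l for l in self.lesions if l.disrupting]

    @property
    def primary_lesions(self) -> list[Lesion]:
        return [l for l in self.lesions if not l.secondary]


# ---------------------------------------------------------------- alignment


def _walk_alignment(aligned_ref: str, aligned_target: str):
    """Yield (column, ref_pos, target_pos, ref_char, target_char)."""
    r = t = 0
    for i, (rc, tc) in enumerate(zip(aligned_ref, aligned_target)):
        yield i, r, t, rc, tc
        if rc != "-":
            r += 1
        if tc != "-":
            t += 1


def _indel_groups(aligned_ref: str, aligned_target: str, merge_gap: int = 3):
    """Gap runs as (ref_offset, target_offset, ref_seq, target_seq).

    Gap runs separated by at most ``merge_gap`` aligned columns are merged
    into one net indel (with the intervening bases included on both sides):
    the optimal alignment of a single indel plus nearby substitutions is
    sometimes a split gap, and the lesion of record is the net event.
    """
    raw = []
    cur = None
    for i, r, t, rc, tc in _walk_alignment(aligned_ref, aligned_target):
        gap = rc == "-" or tc == "-"
        if gap:
            if cur is None:
                cur = {"c0": i, "r": r, "t": t, "ref": [], "tgt": []}
            cur["c1"] = i
            if rc != "-":
                cur["ref"].append(rc)
            if tc != "-":
                cur["tgt"].append(tc)
        elif cur is not None:
            raw.append(cur)
            cur = None
    if cur is not None:
        raw.append(cur)
    merged = []
    for g in raw:
        if merged and g["c0"] - merged[-1]["c1"] - 1 <= merge_gap:
            prev = merged[-1]
            between = g["c0"] - prev["c1"] - 1
            if between > 0:
                seg_r = aligned_ref[prev["c1"] + 1 : g["c0"]]
                seg_t = aligned_target[prev["c1"] + 1 : g["c0"]]
                prev["ref"].extend(seg_r)
                prev["tgt"].extend(seg_t)
            prev["ref"].extend(g["ref"])
            prev["tgt"].extend(g["tgt"])
            prev["c1"] = g["c1"]
        else:
            merged.append(g)
    return [(g["r"], g["t"], "".join(g["ref"]), "".join(g["tgt"])) for g in merged]


def _target_to_ref_map(aligned_ref: str, aligned_target: str) -> list[int]:
    """For each target position, the number of reference bases consumed before it."""
    out = []
    for _, r, t, rc, tc in _walk_alignment(aligned_ref, aligned_target):
        if tc != "-":
            out.append(r)
    return out


def call_exon_lesions(
    hit: ExonHit,
    model: GeneModel,
    cds_offset: Optional[int] = None,
    ref_offset: Optional[int] = None,
    terminal_window: int = 30,
) -> list[Lesion]:
    """Lesions of a single placed exon: indels, premature STOPs, splice mutations.

    ``cds_offset`` is the length of observed CDS assembled upstream of this
    exon (used to place codon boundaries); ``ref_offset`` its reference
    counterpart.  When omitted, the exon is treated as frame-faithful
    (standalone use on a single exon).
    """
    if not hit.found:
        raise ValueError("lesions can only be called on found exons")
    edef = model.exon_by_number(hit.exon_number)
    ref_off = ref_offset if ref_offset is not None else edef.phase
    obs_off = cds_offset if cds_offset is not None else ref_off
    lesions: list[Lesion] = []

    # --- indels from alignment gaps
    groups = _indel_groups(hit.aligned_ref, hit.aligned_target)
    indel_footprints: list[tuple[int, int]] = []  # target-side [start, end)
    for r0, t0, ref_seq, tgt_seq in groups:
        net = len(tgt_seq) - len(ref_seq)
        if net == 0:
            continue
        kind = INFRAME_INDEL if net % 3 == 0 else FRAMESHIFT_INDEL
        lesions.append(
            Lesion(
                kind=kind,
                exon_number=hit.exon_number,
                offset=t0,
                observed=tgt_seq,
                reference=ref_seq,
                disrupting=(kind == FRAMESHIFT_INDEL),
            )
        )
        indel_footprints.append((t0, t0 + max(len(tgt_seq), 1)))

    # --- premature STOPs in the observed reading frame
    target = hit.target_seq
    t2r = _target_to_ref_map(hit.aligned_ref, hit.aligned_target)
    is_stop_exon = model.exons[model.stop_exon].number == hit.exon_number
    frame_consistent_global = (obs_off - ref_off) % 3 == 0
    shift_seen = not frame_consistent_global
    for p in range(len(target) - 2):
        if (obs_off + p) % 3 != 0:
            continue
        codon = target[p : p + 3]
        if codon not in STOP_CODONS:
            continue
        if is_stop_exon and p >= len(target) - terminal_window:
            continue  # the true STOP, merely shifted within the terminal window
        local_ok = (p - t2r[p]) % 3 == 0 if p < len(t2r) else True
        near_indel = any(f0 - 3 < p < f1 + 3 for f0, f1 in indel_footprints)
        secondary = (not frame_consistent_global) or (not local_ok) or near_indel
        lesions.append(
            Lesion(
                kind=PREMATURE_STOP,
                exon_number=hit.exon_number,
                offset=p,
                observed=codon,
                reference=edef.sequence[t2r[p] : t2r[p] + 3] if p < len(t2r) else "",
                disrupting=True,
                secondary=secondary,
            )
        )

    # --- splice-site classification on both flanks
    if edef.expected_donor is not None and hit.donor_dinucleotide is not None:
        call = classify_splice_site(hit.donor_dinucleotide, "donor")
        if call.category == MUTATED:
            lesions.append(
                Lesion(
                    kind=SPLICE_DONOR_MUT,
                    exon_number=hit.exon_number,
                    boundary="donor",
                    observed=hit.donor_dinucleotide,
                    reference=edef.expected_donor,
                    disrupting=True,
                    note="low_confidence" if call.low_confidence else "",
                )
            )
    if edef.expected_acceptor is not None and hit.acceptor_dinucleotide is not None:
        call = classify_splice_site(hit.acceptor_dinucleotide, "acceptor")
        if call.category == MUTATED:
            lesions.append(
                Lesion(
                    kind=SPLICE_ACCEPTOR_MUT,
                    exon_number=hit.exon_number,
                    boundary="acceptor",
                    observed=hit.acceptor_dinucleotide,
                    reference=edef.expected_acceptor,
                    disrupting=True,
                    note="low_confidence" if call.low_confidence else "",
                )
            )
    return lesions


def detect_exon_fusion(
    locus: TargetLocus,
    hit_k: ExonHit,
    hit_k1: ExonHit,
    model: GeneModel,
    cds_offset: Optional[int] = None,
) -> Optional[FusionCall]:
    """Call an in-frame fusion of two adjacent exons ("super exon").

    Requires: the donor of the upstream exon is MUTATED, the intervening
    intron length is a multiple of 3, and reading through the intron in the
    running frame meets no STOP.
    """
    if not (hit_k.found and hit_k1.found):
        return None
    if hit_k.donor_dinucleotide is None:
        return None
    if classify_splice_site(hit_k.donor_dinucleotide, "donor").category != MUTATED:
        return None
    e_k = hit_k.target_interval[1]
    s_k1 = hit_k1.target_interval[0]
    intron_len = s_k1 - e_k
    if intron_len <= 0 or intron_len % 3 != 0:
        return None
    edef = model.exon_by_number(hit_k.exon_number)
    obs_off = cds_offset if cds_offset is not None else edef.phase
    # read through exon_k + intron + start of exon_k1 in the running frame
    s_k = hit_k.target_interval[0]
    e_k1 = hit_k1.target_interval[1]
    stretch = locus.sequence[s_k:e_k1]
    intron_lo = e_k - s_k
    intron_hi = intron_lo + intron_len
    for p in range(len(stretch) - 2):
        if (obs_off + p) % 3 != 0:
            continue
        if stretch[p : p + 3] in STOP_CODONS:
            if p + 3 > intron_lo and p < intron_hi:  # codon touches the intron
                return None
    return FusionCall(
        upstream_exon=hit_k.exon_number,
        downstream_exon=hit_k1.exon_number,
        intron_length=intron_len,
        incorporated_residues=intron_len // 3,
    )


def scan_rescue_splice_site(
    locus: TargetLocus,
    hit: ExonHit,
    side: str,
    window: int = 30,
    cds_offset: Optional[int] = None,
) -> Optional[int]:
    """Nearest frame-preserving canonical splice dinucleotide near a mutated flank.

    Returns the alternative exon boundary (locus coordinate) or None.  The
    shift must be a codon multiple and, where it extends the exon, must not
    introduce a new in-frame STOP.
    """
    if side not in ("donor", "acceptor"):
        raise ValueError("side must be donor or acceptor")
    seq = locus.sequence
    s, e = hit.target_interval
    edef_off = cds_offset if cds_offset is not None else 0
    deltas = sorted(
        (d for d in range(-window, window + 1) if d != 0 and d % 3 == 0), key=abs
    )
    slice_len = e - s
    for d in deltas:
        if side == "donor":
            b = e + d
            if b < s + 3 or b + 2 > len(seq):
                continue
            if seq[b : b + 2] != CANONICAL_DONOR:
                continue
            if d > 0:  # exon gains seq[e:b]; no new in-frame STOP allowed
                gained = seq[e:b]
                off0 = edef_off + slice_len
                if _has_inframe_stop(gained, off0):
                    continue
            return b
        else:
            b = s + d
            if b < 2 or b > e - 3:
                continue
            if seq[b - 2 : b] != CANONICAL_ACCEPTOR:
                continue
            if d < 0:  # exon gains seq[b:s]
                gained = seq[b:s]
                if _has_inframe_stop(gained, edef_off):
                    continue
            return b
    return None


def _has_inframe_stop(segment: str, start_offset: int) -> bool:
    for p in range(len(segment) - 2):
        if (start_offset + p) % 3 == 0 and segment[p : p + 3] in STOP_CODONS:
            return True
    return False


def assemble_cds(
    hits: Sequence[ExonHit],
    lesions: Sequence[Lesion],
    fusions: Sequence[FusionCall],
    model: GeneModel,
    locus: TargetLocus,
    terminal_window: int = 30,
) -> tuple[str, bool, Optional[int]]:
    """Concatenate exon slices (plus fused introns) into the predicted CDS.

    Returns (cds, orf_continuous, first premature STOP position in the CDS
    or None).  The ORF is continuous iff translation meets no STOP before
    the terminal window and at least one STOP inside it.
    """
    found = [h for h in hits if h.found]
    if not found:
        raise AssemblyError("no assembly possible: all exons missing")
    fused_after = {f.upstream_exon: f for f in fusions}
    parts = []
    for i, h in enumerate(found):
        parts.append(locus.sequence[h.target_interval[0] : h.target_interval[1]])
        f = fused_after.get(h.exon_number)
        if f is not None and i + 1 < len(found) and found[i + 1].exon_number == f.downstream_exon:
            parts.append(
                locus.sequence[h.target_interval[1] : found[i + 1].target_interval[0]]
            )
    cds = "".join(parts)
    if len(cds) < 3:
        raise AssemblyError("assembled CDS shorter than one codon")
    aa = translate(cds, 0)
    stops = [i for i, a in enumerate(aa) if a == "*"]
    terminal_codon_start = max(len(aa) - max(1, terminal_window // 3), 0)
    premature = [i for i in stops if i < terminal_codon_start]
    orf_continuous = not premature and any(i >= terminal_codon_start for i in stops)
    first = 3 * premature[0] if premature else None
    return cds, orf_continuous, first


def classify_gene(
    hits: Sequence[ExonHit],
    lesions: Sequence[Lesion],
    fusions: Sequence[FusionCall],
    orf_continuous: bool,
    species_id: str = "",
    gene_id: str = "",
    cds: Optional[str] = None,
) -> GeneVerdict:
    """Issue the per-gene verdict from reconciled lesions and fusion calls."""
    lesions = list(lesions)
    fusions = list(fusions)
    unresolved = any((not h.found) and h.unresolved for h in hits)
    disrupting = [l for l in lesions if l.disrupting]
    if unresolved:
        status = "INCOMPLETE"
    elif disrupting or not orf_continuous:
        status = "PSEUDOGENE"
    elif fusions:
        status = "INTACT_FUSION"
    else:
        status = "INTACT"
    confidence = []
    if status == "PSEUDOGENE" and disrupting and all(
        l.kind in (SPLICE_DONOR_MUT, SPLICE_ACCEPTOR_MUT) for l in disrupting
    ):
        confidence.append("splice_only")
    if any(l.note == "low_confidence" for l in lesions):
        confidence.append("low_confidence_splice")
    return GeneVerdict(
        species_id=species_id,
        gene_id=gene_id,
        status=status,
        lesions=lesions,
        fusions=fusions,
        cds=cds if status != "PSEUDOGENE" else None,
        confidence=confidence,
        hits=list(hits),
    )


# ------------------------------------------------------------ orchestration


def evaluate_locus(
    model: GeneModel,
    locus: TargetLocus,
    params: ScoreParams = ScoreParams(),
    rescue_window: int = 30,
    terminal_window: int = 30,
) -> GeneVerdict:
    """Run the full per-locus analysis: orient, map, call, reconcile, classify."""
    oriented = orient_locus(locus, model, params)
    hits = locate_exons(model, oriented, params)
    by_number = {h.exon_number: h for h in hits}

    lesions: list[Lesion] = []
    fusions: list[FusionCall] = []
    obs_off = 0
    ref_off = 0
    obs_offsets: dict[int, int] = {}
    numbers = [e.number for e in model.exons]
    for i, e in enumerate(model.exons):
        h = by_number[e.number]
        if not h.found:
            if not h.unresolved:
                lesions.append(
                    Lesion(
                        kind=EXON_MISSING,
                        exon_number=e.number,
                        reference=e.sequence,
                        disrupting=True,
                    )
                )
            ref_off += len(e.sequence)
            continue
        obs_offsets[e.number] = obs_off
        lesions.extend(
            call_exon_lesions(
                h, model, cds_offset=obs_off, ref_offset=ref_off,
                terminal_window=terminal_window,
            )
        )
        slice_len = h.target_interval[1] - h.target_interval[0]
        fusion = None
        if i + 1 < len(numbers):
            nxt = by_number[numbers[i + 1]]
            fusion = detect_exon_fusion(oriented, h, nxt, model, cds_offset=obs_off)
            if fusion is not None:
                fusions.append(fusion)
        obs_off += slice_len + (fusion.intron_length if fusion else 0)
        ref_off += len(e.sequence)

    # reconcile splice lesions against fusions and rescue sites
    fused_upstream = {f.upstream_exon for f in fusions}
    fused_downstream = {f.downstream_exon for f in fusions}
    for l in lesions:
        if l.kind == SPLICE_DONOR_MUT and l.exon_number in fused_upstream:
            l.disrupting = False
            l.note = (l.note + ";" if l.note else "") + "fusion"
        elif l.kind == SPLICE_ACCEPTOR_MUT and l.exon_number in fused_downstream:
            l.disrupting = False
            l.note = (l.note + ";" if l.note else "") + "fusion"
        elif l.kind in (SPLICE_DONOR_MUT, SPLICE_ACCEPTOR_MUT):
            h = by_number[l.exon_number]
            side = "donor" if l.kind == SPLICE_DONOR_MUT else "acceptor"
            b = scan_rescue_splice_site(
                oriented, h, side, window=rescue_window,
                cds_offset=obs_offsets.get(l.exon_number),
            )
            if b is not None:
                l.disrupting = False
                l.note = (l.note + ";" if l.note else "") + f"rescue@{b}"

    try:
        cds, orf_continuous, _ = assemble_cds(
            hits, lesions, fusions, model, oriented, terminal_window=terminal_window
        )
    except AssemblyError:
        cds, orf_continuous = None, False
    return classify_gene(
        hits,
        lesions,
        fusions,
        orf_continuous,
        species_id=locus.species_id,
        gene_id=model.gene_id,
        cds=cds,
    )
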