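"""Reference-guided exon placement in target loci.

Each reference exon is located in the (oriented) target locus by local
alignment with affine gap costs, searching only downstream of the previous
exon's hit so that placements are colinear by construction.  Accepted hits
are boundary-snapped to cover the full reference exon, re-aligned globally
to obtain a gapped alignment for lesion calling, and annotated with the
splice dinucleotides read from the flanking intronic sequence.

This is the in-memory equivalent of a BLAST-against-contigs plus
template-anchored multiple-alignment reconstruction step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

from Bio import Align

from .gene_model import GeneModel, TargetLocus, reverse_complement


class NoGeneFoundError(RuntimeError):
    """Neither strand of the locus contains an acceptable exon hit."""


@dataclass(frozen=True)
class ScoreParams:
    """BLAST-like scoring for within-order mammalian divergence.

    A gap of length L costs ``open + extend * L``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_identity: float = 0.6
    min_coverage: float = 0.6  # fraction of the exon that must align
    lookback: int = 50  # tolerated micro-overlap with the previous hit
    n_run_threshold: int = 50  # N runs >= this mark exons unresolvable
    orient_sample: int = 4  # longest exons used for strand resolution (0 = all)


@dataclass
class ExonHit:
    """Placement and alignment of one reference exon in a target locus."""

    exon_number: int
    found: bool
    target_interval: Optional[tuple[int, int]] = None  # 0-based half-open
    aligned_ref: str = ""
    aligned_target: str = ""
    identity: float = 0.0
    donor_dinucleotide: Optional[str] = None
    acceptor_dinucleotide: Optional[str] = None
    unresolved: bool = False  # absent because of assembly gaps (N runs)

    @property
    def target_seq(self) -> str:
        return self.aligned_target.replace("-", "")


def _make_aligner(params: ScoreParams, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    # biopython charges open for the first gap base, extend for the rest
    al.open_gap_score = params.gap_open + params.gap_extend
    al.extend_gap_score = params.gap_extend
    return al


def _best_local(aligner, window: str, ref: str):
    """Best local alignment (leftmost among co-optimal); None if score <= 0."""
    if not window or not ref:
        return None
    alns = aligner.align(window, ref)
    try:
        aln = alns[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    return aln


def _identity_and_spans(aln) -> tuple[float, int, tuple[int, int], tuple[int, int]]:
    """(identity, aligned ref length, target span, ref span) of an alignment."""
    tblocks, qblocks = aln.aligned
    target = aln.sequences[0]
    query = aln.sequences[1]
    matches = 0
    cols = 0
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        for i in range(t1 - t0):
            cols += 1
            if target[t0 + i] == query[q0 + i]:
                matches += 1
    # gap columns between blocks count against identity
    if len(tblocks):
        span_t = int(tblocks[-1][1] - tblocks[0][0])
        span_q = int(qblocks[-1][1] - qblocks[0][0])
        cols += (span_t - sum(int(b[1] - b[0]) for b in tblocks)) + (
            span_q - sum(int(b[1] - b[0]) for b in qblocks)
        )
        tspan = (int(tblocks[0][0]), int(tblocks[-1][1]))
        qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    else:
        return 0.0, 0, (0, 0), (0, 0)
    ident = matches / cols if cols else 0.0
    ref_alen = sum(int(b[1] - b[0]) for b in qblocks)
    return ident, ref_alen, tspan, qspan


def _gapped_rows(aln, end_gaps: bool = True) -> tuple[str, str]:
    """Gapped (target, query) alignment strings.

    With ``end_gaps`` (global alignments), unaligned sequence ends are
    emitted as gap columns so that edge indels stay visible to lesion
    calling; without it only the aligned region is returned.
    """
    tblocks, qblocks = aln.aligned
    target = aln.sequences[0]
    query = aln.sequences[1]
    t_out, q_out = [], []
    pt, pq = (0, 0) if end_gaps else (tblocks[0][0], qblocks[0][0])
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        if t0 > pt:
            t_out.append(target[pt:t0])
            q_out.append("-" * (t0 - pt))
        if q0 > pq:
            q_out.append(query[pq:q0])
            t_out.append("-" * (q0 - pq))
        t_out.append(target[t0:t1])
        q_out.append(query[q0:q1])
        pt, pq = t1, q1
    if end_gaps:
        if pt < len(target):
            t_out.append(target[pt:])
            q_out.append("-" * (len(target) - pt))
        if pq < len(query):
            q_out.append(query[pq:])
            t_out.append("-" * (len(query) - pq))
    return "".join(t_out), "".join(q_out)


def _accepts(params: ScoreParams, identity: float, ref_alen: int, exon_len: int) -> bool:
    return identity >= params.min_identity and ref_alen >= params.min_coverage * exon_len


def orient_locus(
    locus: TargetLocus, model: GeneModel, params: ScoreParams = ScoreParams()
) -> TargetLocus:
    """Resolve the strand on which the gene lies.

    The strand whose summed best-exon local-alignment score is higher wins;
    if neither strand yields a single acceptable exon hit the locus does not
    contain the gene.
    """
    longest = max(len(e.sequence) for e in model.exons)
    if len(locus.sequence) < longest:
        raise NoGeneFoundError(f"locus {locus.locus_id} shorter than the longest exon")
    aligner = _make_aligner(params, "local")
    exons = list(model.exons)
    if params.orient_sample and len(exons) > params.orient_sample:
        exons = sorted(exons, key=lambda e: -len(e.sequence))[: params.orient_sample]
    results = {}
    for strand, seq in (
        ("forward", locus.sequence),
        ("reverse", reverse_complement(locus.sequence)),
    ):
        total = 0.0
        any_ok = False
        for e in exons:
            aln = _best_local(aligner, seq, e.sequence)
            if aln is None:
                continue
            total += aln.score
            ident, ref_alen, _, _ = _identity_and_spans(aln)
            if _accepts(params, ident, ref_alen, len(e.sequence)):
                any_ok = True
        results[strand] = (total, any_ok)
    if not results["forward"][1] and not results["reverse"][1]:
        raise NoGeneFoundError(f"no gene found in locus {locus.locus_id}")
    strand = "forward" if results["forward"][0] >= results["reverse"][0] else "reverse"
    seq = locus.sequence if strand == "forward" else reverse_complement(locus.sequence)
    return TargetLocus(
        species_id=locus.species_id,
        locus_id=locus.locus_id,
        sequence=seq,
        orientation=strand,
    )


def locate_exons(
    model: GeneModel, locus: TargetLocus, params: ScoreParams = ScoreParams()
) -> list[ExonHit]:
    """Place every reference exon in the oriented locus, colinearly.

    Absence is data: an exon with no acceptable alignment in its search
    window is returned with ``found=False`` (and ``unresolved=True`` when
    the window is interrupted by a long N run, i.e. an assembly gap).
    """
    seq = locus.sequence
    local = _make_aligner(params, "local")
    glob = _make_aligner(params, "global")
    hits: list[ExonHit] = []
    prev_end = 0
    for e in model.exons:
        w0 = max(prev_end - params.lookback, 0)
        window = seq[w0:]
        aln = _best_local(local, window, e.sequence)
        ok = False
        if aln is not None:
            ident, ref_alen, tspan, qspan = _identity_and_spans(aln)
            ok = _accepts(params, ident, ref_alen, len(e.sequence))
        if not ok:
            unresolved = _has_n_run(window, params.n_run_threshold)
            hits.append(ExonHit(exon_number=e.number, found=False, unresolved=unresolved))
            continue
        # snap boundaries so the interval covers the full reference exon
        start = w0 + tspan[0] - qspan[0]
        end = w0 + tspan[1] + (len(e.sequence) - qspan[1])
        start = max(start, prev_end if hits and hits[-1].found else 0, 0)
        end = min(end, len(seq))
        gal = glob.align(seq[start:end], e.sequence)[0]
        grow_t, grow_q = _gapped_rows(gal)
        gident, _, _, _ = _identity_and_spans(gal)
        hit = ExonHit(
            exon_number=e.number,
            found=True,
            target_interval=(start, end),
            aligned_ref=grow_q,
            aligned_target=grow_t,
            identity=gident,
        )
        hit.acceptor_dinucleotide, hit.donor_dinucleotide = extract_splice_dinucleotides(
            locus, hit
        )
        hits.append(hit)
        prev_end = end
    return hits


def _has_n_run(window: str, threshold: int) -> bool:
    return bool(re.search("N{%d,}" % threshold, window))


def extract_splice_dinucleotides(
    locus: TargetLocus, hit: ExonHit
) -> tuple[Optional[str], Optional[str]]:
    """(acceptor, donor) 2-mers flanking the exon interval; None at locus edges."""
    if not hit.found or hit.target_interval is None:
        raise ValueError("cannot extract splice context for an absent exon")
    s, e = hit.target_interval
    seq = locus.sequence
    acceptor = seq[s - 2 : s] if s >= 2 else None
    donor = seq[e : e + 2] if e + 2 <= len(seq) else None
    return acceptor, donor


# -------------------------------------------------------------------- export


def hits_to_bed(hits: list[ExonHit], locus: TargetLocus) -> str:
    """Exon placements as BED (0-based half-open)."""
    lines = []
    for h in hits:
        if not h.found:
            continue
        s, e = h.target_interval
        lines.append(f"{locus.locus_id}\t{s}\t{e}\texon{h.exon_number}\t0\t+")
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_tsv(hits: list[ExonHit], locus: TargetLocus) -> str:
    """Alignment report, 1-based inclusive coordinates for human readers."""
    rows = ["species\tlocus\texon\tfound\tstart\tend\tidentity\tacceptor\tdonor"]
    for h in hits:
        if h.found:
            s, e = h.target_interval
            rows.append(
                f"{locus.species_id}\t{locus.locus_id}\t{h.exon_number}\tyes\t"
                f"{s + 1}\t{e}\t{h.identity:.4f}\t{h.acceptor_dinucleotide or '.'}\t"
                f"{h.donor_dinucleotide or '.'}"
            )
        else:
            flag = "gap" if h.unresolved else "no"
            rows.append(
                f"{locus.species_id}\t{locus.locus_id}\t{h.exon_number}\t{flag}\t.\t.\t.\t.\t."
            )
    return "\n".join(rows) + "\n"
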