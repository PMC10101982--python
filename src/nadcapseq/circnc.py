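"""circNC junction analysis: from amplicon read pairs to cap-addition sites.

A circularized, decapped transcript read across its 5'/3' junction yields an
amplicon of the form ``3' segment + polyA tail + 5' segment``, where the 5'
segment begins at the cap-addition site. The operations here recover that
structure at nucleotide precision:

1. :func:`merge_pair` joins overlapping read pairs into a single junction
   read (best-overlap consensus merging).
2. :func:`filter_polya` keeps reads containing a run of at least 8 A's
   (testing the reverse complement when orientation is unresolved).
3. :func:`rank_unique_reads` counts exact-duplicate reads and keeps the
   top-k most abundant unique sequences.
4. :func:`semiglobal_align` aligns a junction flank to the reference
   transcript (global on the query, free end-gaps on the reference,
   affine gap costs).
5. :func:`call_junction` splits a read at its polyA run, aligns both
   flanks, and reports the cap-addition site, 3'-end site and tail length.
6. :func:`classify_cap_site` compares the called cap site with the
   reference base: an A is consistent with co-transcriptional (ab initio)
   cap incorporation; any other base implies post-transcriptional capping.

Coordinates are 0-based half-open internally and 1-based inclusive in
user-facing reports.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from nadcapseq.errors import CoordinateError, InputError, NoJunctionError
from nadcapseq.simdata import TranscriptModel, revcomp

_VALID_SEQ = re.compile(r"^[ACGTN]+$")
_NEG = -(1 << 40)  # effectively -infinity for int64 DP


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class JunctionRead:
    """A candidate junction-spanning read (raw mate or merged pair)."""

    read_id: str
    sequence: str
    source: str = "merged"  # read1 | read2 | merged
    orientation_resolved: bool = False
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"{self.read_id}: empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            raise InputError(f"{self.read_id}: sequence contains non-ACGTN characters")


@dataclass
class PolyARun:
    """A maximal run of consecutive A bases, [start, end) within the read."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ScoringScheme:
    """Affine-gap alignment scores; a gap of length k costs open + k*extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise InputError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise InputError("mismatch and gap penalties must be <= 0")


@dataclass
class AlignmentResult:
    """One flank-to-reference alignment.

    ``operations`` is run-length encoded with '=' match, 'X' mismatch,
    'I' insertion to the reference (query-consuming gap) and 'D' deletion
    (reference-consuming gap). ``aligned_columns`` counts '=' + 'X'.
    """

    score: int
    query_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    operations: list[tuple[str, int]]
    identity: float

    @property
    def aligned_columns(self) -> int:
        return sum(n for op, n in self.operations if op in "=X")


@dataclass
class JunctionCall:
    """A resolved circNC junction for one (representative) read.

    ``cap_site`` and ``three_prime_site`` are 0-based transcript
    coordinates (the first capped base and the last transcribed base);
    ``polya_len`` is a lower-bound tail-length estimate (the observed run
    may be truncated by the read end). ``ambiguous_alt_sites`` lists
    alternative upstream cap sites when the reference continues in A
    immediately 5' of the called site — a templated A at the junction edge
    is absorbed into the maximal polyA run, so those placements are
    indistinguishable from sequence alone.
    """

    read_id: str
    gene_id: str
    representative_sequence: str
    cap_site: int | None
    three_prime_site: int | None
    polya_len: int
    confidence: str  # high | low | none
    five_flank_alignment: AlignmentResult | None = None
    three_flank_alignment: AlignmentResult | None = None
    support_count: int = 1
    support_fraction: float = float("nan")
    ambiguous_alt_sites: list[int] = field(default_factory=list)
    source: str = "merged"


@dataclass
class CapSiteClassification:
    """Cap-addition site vs. the reference base on the coding strand."""

    gene_id: str
    cap_site: int
    ref_base: str
    category: str  # adenosine_consistent | non_adenosine


# ---------------------------------------------------------------------------
# read merging
# ---------------------------------------------------------------------------


def merge_pair(
    r1: JunctionRead,
    r2: JunctionRead,
    min_overlap: int = 12,
    max_mismatch_frac: float = 0.1,
) -> JunctionRead | None:
    """Merge a read pair by its best 3'-of-r1 / 5'-of-rc(r2) overlap.

    ``r2`` is given in sequencing orientation and reverse-complemented
    internally. Every candidate offset is scored (+1 match, -1 mismatch over
    the overlap); offsets with overlap < ``min_overlap`` or mismatch
    fraction > ``max_mismatch_frac`` are rejected. Best overlap = maximal
    score, ties broken toward the longest overlap, then the leftmost offset.
    At conflicting overlap positions the higher-quality base wins (r1 on
    quality ties). Returns None when no acceptable overlap exists.
    """
    s1 = r1.sequence
    s2 = revcomp(r2.sequence)
    q1 = r1.quality or "I" * len(s1)
    q2 = (r2.quality or "I" * len(r2.sequence))[::-1]

    a1 = np.frombuffer(s1.encode(), dtype="S1")
    a2 = np.frombuffer(s2.encode(), dtype="S1")
    best = None  # (score, overlap_len, -offset)
    best_offset = None
    for offset in range(0, len(s1) - min_overlap + 1):
        ov = min(len(s1) - offset, len(s2))
        if ov < min_overlap:
            continue
        mism = int(np.count_nonzero(a1[offset : offset + ov] != a2[:ov]))
        if mism / ov > max_mismatch_frac:
            continue
        key = ((ov - mism) - mism, ov, -offset)
        if best is None or key > best:
            best = key
            best_offset = offset
    if best_offset is None:
        return None

    offset = best_offset
    ov = min(len(s1) - offset, len(s2))
    cons, cq = [], []
    for i in range(ov):
        a, b = s1[offset + i], s2[i]
        if a == b:
            cons.append(a)
            cq.append(max(q1[offset + i], q2[i]))
        elif q2[i] > q1[offset + i]:
            cons.append(b)
            cq.append(q2[i])
        else:
            cons.append(a)
            cq.append(q1[offset + i])
    merged_seq = s1[:offset] + "".join(cons) + s2[ov:]
    merged_qual = q1[:offset] + "".join(cq) + q2[ov:]
    rid = r1.read_id.rsplit("/", 1)[0]
    return JunctionRead(
        read_id=rid,
        sequence=merged_seq,
        source="merged",
        orientation_resolved=True,
        quality=merged_qual,
    )


def quality_trim(read: JunctionRead, window: int = 4, min_q: int = 20) -> JunctionRead:
    """Optional 3' quality trim: cut where a sliding mean drops below min_q.

    Scans windows from the 3' end and trims the suffix from the first
    (3'-most) window whose mean phred quality is below ``min_q``. A
    pluggable pre-step, off by default in the pipeline; reads without
    quality strings are returned unchanged.
    """
    if read.quality is None or len(read.sequence) < window:
        return read
    q = np.frombuffer(read.quality.encode(), dtype=np.uint8).astype(float) - 33
    cut = len(q)
    for start in range(len(q) - window, -1, -1):
        if q[start : start + window].mean() < min_q:
            cut = start
        else:
            break
    while cut < len(q) and q[cut] >= min_q:  # keep good bases at the boundary
        cut += 1
    if cut == len(q):
        return read
    if cut == 0:
        raise InputError(f"{read.read_id}: read entirely below quality threshold")
    return JunctionRead(
        read.read_id, read.sequence[:cut], read.source,
        read.orientation_resolved, read.quality[:cut],
    )


# ---------------------------------------------------------------------------
# polyA filtering
# ---------------------------------------------------------------------------


def find_polya_run(seq: str, min_len: int = 8) -> PolyARun | None:
    """Longest maximal run of consecutive A's with length >= min_len.

    Ties go to the leftmost run; returns None when no run qualifies.
    """
    if not seq:
        raise InputError("empty sequence")
    best: PolyARun | None = None
    for m in re.finditer(r"A+", seq):
        if m.end() - m.start() >= min_len:
            if best is None or m.end() - m.start() > best.length:
                best = PolyARun(m.start(), m.end())
    return best


def filter_polya(reads: Sequence[JunctionRead], min_len: int = 8) -> list[JunctionRead]:
    """Keep reads containing a >= ``min_len`` A run.

    Orientation-unresolved reads are additionally tested as their reverse
    complement (an 8-T run in the given orientation); such reads are
    reverse-complemented in the output and marked resolved.
    """
    out = []
    for read in reads:
        if find_polya_run(read.sequence, min_len) is not None:
            out.append(read)
        elif not read.orientation_resolved and find_polya_run(
            revcomp(read.sequence), min_len
        ) is not None:
            out.append(
                JunctionRead(
                    read_id=read.read_id,
                    sequence=revcomp(read.sequence),
                    source=read.source,
                    orientation_resolved=True,
                    quality=read.quality[::-1] if read.quality else None,
                )
            )
    return out


def rank_unique_reads(
    reads: Sequence[JunctionRead | str], k: int = 5
) -> list[tuple[str, int]]:
    """Top-k most abundant unique read sequences with their multiplicities.

    Ranked by count descending, ties broken lexicographically ascending.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    counts = Counter(seqs)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _check_seq(seq: str, what: str) -> None:
    if not seq:
        raise InputError(f"empty {what} sequence")
    if not _VALID_SEQ.match(seq):
        raise InputError(f"{what} contains non-nucleotide characters")


def semiglobal_align(
    query: str,
    reference: str,
    scheme: ScoringScheme | None = None,
    free_query_start: bool = False,
    free_query_end: bool = False,
) -> AlignmentResult:
    """Optimal affine-gap alignment, global on the query, local on the reference.

    Leading and trailing reference bases are free (semiglobal); every query
    base is aligned or gap-penalized. N scores as a mismatch against
    anything. Traceback is deterministic: ties prefer diagonal, then the
    query-consuming gap, then the reference-consuming gap, and the
    alignment ends at the leftmost optimal reference position.

    ``free_query_start`` / ``free_query_end`` additionally soft-clip an
    unaligned query prefix / suffix at zero cost (used by junction calling
    to shed polyA-run remnants created by sequencing errors); both default
    to off, giving the fully query-global mode.
    """
    if scheme is None:
        scheme = ScoringScheme()
    _check_seq(query, "query")
    _check_seq(reference, "reference")

    m, n = len(query), len(reference)
    q = np.frombuffer(query.encode(), dtype="S1")
    r = np.frombuffer(reference.encode(), dtype="S1")
    go, ge = scheme.gap_open, scheme.gap_extend
    j_idx = np.arange(n + 1, dtype=np.int64)

    M = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    X = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # query-consuming gap
    Y = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # reference-consuming gap
    M[0, :] = 0  # free leading reference gap / alignment start

    for i in range(1, m + 1):
        sub = np.where((r == q[i - 1]) & (q[i - 1] != b"N"), scheme.match, scheme.mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        if free_query_start:
            prev_best = np.maximum(prev_best, 0)
        M[i, 1:] = sub.astype(np.int64) + prev_best[:-1]
        M[i, 0] = _NEG
        X[i] = np.maximum(
            np.maximum(M[i - 1], Y[i - 1]) + go + ge, X[i - 1] + ge
        )
        # Y along the row via a running-max recurrence
        t = np.maximum(M[i], X[i]) + go - ge * j_idx
        Y[i, 1:] = ge * j_idx[1:] + np.maximum.accumulate(t)[:-1]
        Y[i, 0] = _NEG

    if free_query_end:
        # stop consuming query anywhere; prefer the most query aligned,
        # then the leftmost reference end
        best = (_NEG - 1, -1, -1)
        for i in range(m, -1, -1):
            row = M[i] if i > 0 else np.zeros(n + 1, dtype=np.int64)
            jj = int(np.argmax(row))
            if int(row[jj]) > best[0]:
                best = (int(row[jj]), i, jj)
        score, end_i, j = best
        state = "M"
    else:
        end_scores = np.maximum(M[m], X[m])
        j = int(np.argmax(end_scores))  # leftmost optimal end
        score = int(end_scores[j])
        end_i = m
        state = "M" if M[m, j] >= X[m, j] else "X"

    # traceback by score recomputation; tie preference M > X > Y throughout
    ops: list[str] = []
    i = end_i
    ref_end = j
    query_end = end_i
    query_start = 0
    while i > 0:
        if state == "M":
            s = scheme.match if (query[i - 1] == reference[j - 1] != "N") else scheme.mismatch
            ops.append("=" if s == scheme.match and query[i - 1] == reference[j - 1] else "X")
            target = M[i, j] - s
            i, j = i - 1, j - 1
            nxt = None
            for cand, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if val == target:
                    nxt = cand
                    break
            if nxt is None and free_query_start and target == 0:
                query_start = i  # soft-clipped prefix
                break
            state = nxt
        elif state == "X":
            ops.append("I")
            target = X[i, j] - ge
            i -= 1
            if M[i, j] + go == target:
                state = "M"
            elif X[i, j] == target:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            ops.append("D")
            target = Y[i, j] - ge
            j -= 1
            if M[i, j] + go == target:
                state = "M"
            elif X[i, j] + go == target:
                state = "X"
            else:
                state = "Y"
    ref_start = j

    ops.reverse()
    rle: list[tuple[str, int]] = []
    for op in ops:
        if rle and rle[-1][0] == op:
            rle[-1] = (op, rle[-1][1] + 1)
        else:
            rle.append((op, 1))
    matches = sum(n_ for op, n_ in rle if op == "=")
    aligned = sum(n_ for op, n_ in rle if op in "=X")
    identity = matches / aligned if aligned else 0.0
    return AlignmentResult(
        score=score,
        query_interval=(query_start, query_end),
        ref_interval=(ref_start, ref_end),
        operations=rle,
        identity=identity,
    )


def rescore_alignment(result: AlignmentResult, scheme: ScoringScheme) -> int:
    """Recompute an alignment's score from its edit operations."""
    total = 0
    for op, n in result.operations:
        if op == "=":
            total += scheme.match * n
        elif op == "X":
            total += scheme.mismatch * n
        else:
            total += scheme.gap_open + scheme.gap_extend * n
    return total


# ---------------------------------------------------------------------------
# junction calling
# ---------------------------------------------------------------------------


def _flank_ok(aln: AlignmentResult, min_flank: int, min_identity: float) -> bool:
    return aln.aligned_columns >= min_flank and aln.identity >= min_identity


def _leading_tail_columns(aln: AlignmentResult, query: str) -> int:
    """Matched A columns at the start of a 5'-flank alignment.

    A query A matching a reference A right at the junction cannot be told
    apart from a polyA-tail base (the tail is untemplated A's); boundary
    attribution is tail-first, so such columns are assigned to the tail and
    the cap site moves past them.
    """
    k = 0
    qi = aln.query_interval[0]
    for op, n in aln.operations:
        if op != "=":
            break
        for _ in range(n):
            if query[qi] != "A":
                return k
            k += 1
            qi += 1
    return k


def _trailing_tail_columns(aln: AlignmentResult, query: str) -> int:
    """Matched A columns at the end of a 3'-flank alignment (mirror case)."""
    k = 0
    qi = aln.query_interval[1] - 1
    for op, n in reversed(aln.operations):
        if op != "=":
            break
        for _ in range(n):
            if query[qi] != "A":
                return k
            k += 1
            qi -= 1
    return k


def call_junction(
    read: JunctionRead,
    model: TranscriptModel,
    scheme: ScoringScheme | None = None,
    min_flank: int = 15,
    min_identity: float = 0.9,
    min_polya: int = 8,
    max_alt_sites: int = 3,
) -> JunctionCall:
    """Resolve the circNC junction of one polyA-containing read.

    The read is split at its polyA run; the post-run segment is aligned to
    the transcript (its start is the cap-addition site) and the pre-run
    segment likewise (its end is the transcript 3' end). Confidence is
    ``high`` when both flanks have >= ``min_flank`` aligned bases at
    >= ``min_identity`` identity, ``low`` when exactly one qualifies (the
    qualifying site is still reported), ``none`` otherwise.
    """
    if scheme is None:
        scheme = ScoringScheme()
    run = find_polya_run(read.sequence, min_polya)
    if run is None:
        raise NoJunctionError(f"{read.read_id}: no polyA run of >= {min_polya}")

    pre = read.sequence[: run.start]
    post = read.sequence[run.end :]

    # the run-adjacent query end is soft-clipped: a substitution inside the
    # polyA tail splits the run and leaves an A remnant on one flank, which
    # must not drag the boundary alignment off the true site
    aln5 = (
        semiglobal_align(post, model.sequence, scheme, free_query_start=True)
        if post
        else None
    )
    aln3 = (
        semiglobal_align(pre, model.sequence, scheme, free_query_end=True)
        if pre
        else None
    )
    ok5 = aln5 is not None and _flank_ok(aln5, min_flank, min_identity)
    ok3 = aln3 is not None and _flank_ok(aln3, min_flank, min_identity)

    cap_site = None
    if ok5:
        cap_site = aln5.ref_interval[0] + _leading_tail_columns(aln5, post)
        cap_site = min(cap_site, aln5.ref_interval[1] - 1)
    three_prime_site = None
    if ok3:
        three_prime_site = aln3.ref_interval[1] - 1 - _trailing_tail_columns(aln3, pre)
        three_prime_site = max(three_prime_site, aln3.ref_interval[0])
    confidence = "high" if (ok5 and ok3) else ("low" if (ok5 or ok3) else "none")

    alt_sites: list[int] = []
    if cap_site is not None:
        p = cap_site - 1
        while p >= 0 and model.sequence[p] == "A" and len(alt_sites) < max_alt_sites:
            alt_sites.append(p)
            p -= 1

    return JunctionCall(
        read_id=read.read_id,
        gene_id=model.gene_id,
        representative_sequence=read.sequence,
        cap_site=cap_site,
        three_prime_site=three_prime_site,
        polya_len=run.length,
        confidence=confidence,
        five_flank_alignment=aln5,
        three_flank_alignment=aln3,
        ambiguous_alt_sites=alt_sites,
        source=read.source,
    )


def classify_cap_site(call: JunctionCall, model: TranscriptModel) -> CapSiteClassification:
    """Compare a called cap-addition site with the reference coding-strand base.

    An A at the cap site is consistent with ab initio incorporation of the
    non-canonical cap as the first transcribed nucleotide; any other base
    implies the cap was added post-transcriptionally.
    """
    if call.confidence == "none":
        raise InputError("cannot classify a no-confidence junction call")
    if call.cap_site is None or not 0 <= call.cap_site < len(model.sequence):
        raise CoordinateError(
            f"cap site {call.cap_site} outside transcript {model.gene_id} "
            f"of length {len(model.sequence)}"
        )
    ref_base = model.sequence[call.cap_site]
    category = "adenosine_consistent" if ref_base == "A" else "non_adenosine"
    return CapSiteClassification(
        gene_id=model.gene_id,
        cap_site=call.cap_site,
        ref_base=ref_base,
        category=category,
    )


# ---------------------------------------------------------------------------
# per-gene summaries
# ---------------------------------------------------------------------------


def summarize_junctions(
    calls_by_treatment: Mapping[str, Sequence[JunctionCall]], k: int = 5
) -> dict:
    """Summarize junction calls for one gene across treatments.

    For each treatment (e.g. ``Rai1`` = NAD caps, ``MDE`` = m7G caps):
    the top-k representative sequences with support fractions over all
    junction-spanning reads of that treatment, the predominant cap site,
    and 3'-site / polyA-length medians. ``same_tss`` compares the
    predominant cap sites of the first two treatments (None unless both
    are defined).
    """
    summary: dict = {"treatments": {}, "same_tss": None}
    predominant: dict[str, int | None] = {}
    for treatment, calls in calls_by_treatment.items():
        calls = list(calls)
        total = sum(c.support_count for c in calls)
        by_seq: Counter = Counter()
        rep: dict[str, JunctionCall] = {}
        for c in calls:
            by_seq[c.representative_sequence] += c.support_count
            rep.setdefault(c.representative_sequence, c)
        ranked = sorted(by_seq.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        top = []
        for rank, (seq, count) in enumerate(ranked, start=1):
            c = rep[seq]
            top.append(
                {
                    "rank": rank,
                    "sequence": seq,
                    "count": count,
                    "fraction": count / total if total else 0.0,
                    "cap_site": c.cap_site,
                    "three_prime_site": c.three_prime_site,
                    "polya_len": c.polya_len,
                    "confidence": c.confidence,
                }
            )
        site_votes: Counter = Counter()
        for c in calls:
            if c.cap_site is not None and c.confidence != "none":
                site_votes[c.cap_site] += c.support_count
        if site_votes:
            best_count = max(site_votes.values())
            pred = min(s for s, n in site_votes.items() if n == best_count)
        else:
            pred = None
        predominant[treatment] = pred
        sites_3p = [c.three_prime_site for c in calls if c.three_prime_site is not None]
        polyas = [c.polya_len for c in calls]
        summary["treatments"][treatment] = {
            "n_reads": total,
            "top": top,
            "predominant_cap_site": pred,
            "median_three_prime_site": float(np.median(sites_3p)) if sites_3p else None,
            "median_polya_len": float(np.median(polyas)) if polyas else None,
        }
    treatments = list(calls_by_treatment)
    if len(treatments) >= 2:
        a, b = predominant.get(treatments[0]), predominant.get(treatments[1])
        if a is not None and b is not None:
            summary["same_tss"] = a == b
    return summary


# ---------------------------------------------------------------------------
# stream driver
# ---------------------------------------------------------------------------


def process_read_pairs(
    pairs: Sequence[tuple],
    model: TranscriptModel,
    scheme: ScoringScheme | None = None,
    min_overlap: int = 12,
    max_mismatch_frac: float = 0.1,
    min_polya: int = 8,
    min_flank: int = 15,
    min_identity: float = 0.9,
) -> dict:
    """Run the circNC analysis on read pairs for one gene/treatment.

    Read 1, read 2 and the merged reads are processed as three separate
    streams: polyA-filter, unique-read counting, then one junction call per
    unique sequence carrying its support count and fraction. Returns
    ``{"streams": {name: [JunctionCall, ...]}, "stage_counts": {...}}``;
    per-gene summaries should prefer the merged stream when nonempty.
    """
    scheme = scheme or ScoringScheme()
    r1 = [
        JunctionRead(p[0].read_id, p[0].sequence, "read1", False, p[0].quality)
        for p in pairs
    ]
    r2 = [
        JunctionRead(p[1].read_id, p[1].sequence, "read2", False, p[1].quality)
        for p in pairs
    ]
    merged = []
    for a, b in zip(r1, r2):
        m = merge_pair(a, b, min_overlap, max_mismatch_frac)
        if m is not None:
            merged.append(m)

    streams = {"merged": merged, "read1": r1, "read2": r2}
    calls: dict[str, list[JunctionCall]] = {}
    stage_counts: dict[str, dict[str, int]] = {}
    for name, reads in streams.items():
        passing = filter_polya(reads, min_polya)
        total = len(passing)
        stage_counts[name] = {"input": len(reads), "polya_pass": total}
        ranked = rank_unique_reads(passing, k=max(1, total)) if passing else []
        source = name
        stream_calls = []
        for seq, count in ranked:
            call = call_junction(
                JunctionRead(f"{model.gene_id}:{name}", seq, source, True),
                model,
                scheme,
                min_flank=min_flank,
                min_identity=min_identity,
                min_polya=min_polya,
            )
            call.support_count = count
            call.support_fraction = count / total
            stream_calls.append(call)
        calls[name] = stream_calls
        stage_counts[name]["unique"] = len(stream_calls)
    return {"streams": calls, "stage_counts": stage_counts}
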