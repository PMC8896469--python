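"""Merged-read processing: trimming, structure parsing, gene sorting,
spike-in classification and per-read variant observations.

A merged read has the layout::

    [14 nt primary barcode][4 nt ID-1][insert][5 nt secondary barcode][4 nt ID-2]

The primary barcode tags the original molecule (its family), the secondary
barcode tags each linear-amplification copy, and ID-1/ID-2 identify donor
and treatment.  Processing mirrors the upstream pipeline the method was
designed around: sliding-window quality trimming (window 3, Phred 30),
edge trimming with identifier validation, gene sorting on the hexamer at
CDS 33-38 (one mismatch, frame shifts of up to +/-3 allowed), then global
alignment to the ROI reference with SNVs accepted only at base quality
>= 28 (Phred+33 throughout).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from . import refmodel
from .refmodel import MutationEvent, ROIModel

__all__ = [
    "StructuredRead",
    "ReadVariantObservation",
    "UnalignableRead",
    "quality_trim",
    "parse_structure",
    "assign_gene",
    "classify_spike_in",
    "align_and_call",
    "read_fastq",
    "process_reads",
]

PRIMARY_BC_LEN = 14
ID1_LEN = 4
SECONDARY_BC_LEN = 5
ID2_LEN = 4
HEAD_LEN = PRIMARY_BC_LEN + ID1_LEN  # 18: the trimmed 5' edge
TAIL_LEN = SECONDARY_BC_LEN + ID2_LEN  # 9: the trimmed 3' edge

DEFAULT_SPIKE_VARIANTS = ("TTATGTT", "ACGAGAC")


class UnalignableRead(Exception):
    """Insert could not be aligned to the reference above the identity floor."""


@dataclass(slots=True)
class StructuredRead:
    read_id: str
    primary_barcode: str
    id1: str
    insert: str
    quals: str  # Phred+33, same length as insert
    secondary_barcode: str
    id2: str
    gene_assignment: str = "unassigned"  # gene id or "unassigned"
    spike_variant: str | None = None  # resistant spike-in heptamer, if any
    donor: str | None = None
    treatment: str | None = None
    reject_reason: str | None = None
    observations: list = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return self.reject_reason is None


@dataclass(frozen=True, slots=True)
class ReadVariantObservation:
    mutation: MutationEvent
    phred: int
    read_id: str
    in_site: bool


def quality_trim(
    bases: str, quals: Iterable[int], window: int = 3, threshold: int = 30
) -> tuple[str, list[int]]:
    """Sliding-window 3' trim (Trimmomatic SLIDINGWINDOW semantics).

    Scanning from the 5' end, the read is cut at the first window whose mean
    quality drops below the threshold, then individually good bases at the
    cut point are retained while their quality stays >= threshold.
    """
    quals = list(quals)
    if len(bases) != len(quals):
        raise ValueError("bases and quals must have equal length")
    n = len(bases)
    if n < window:
        return bases, quals
    acc = sum(quals[:window])
    cut = None
    for i in range(n - window + 1):
        if i > 0:
            acc += quals[i + window - 1] - quals[i - 1]
        if acc < threshold * window:
            cut = i
            break
    if cut is None:
        return bases, quals
    while cut < n and quals[cut] >= threshold:
        cut += 1
    return bases[:cut], quals[:cut]


_resolve_cache: dict[int, tuple] = {}


def _resolve_ids(ids) -> tuple[frozenset, Mapping | None]:
    """Accept either a set of identifier sequences or a mapping
    identifier -> (donor, treatment).  Resolution is cached by object
    identity so per-read calls stay cheap."""
    hit = _resolve_cache.get(id(ids))
    if hit is not None and hit[2] is ids:
        return hit[0], hit[1]
    if isinstance(ids, Mapping):
        out = (frozenset(ids), ids, ids)
    else:
        out = (frozenset(ids), None, ids)
    if len(_resolve_cache) > 64:
        _resolve_cache.clear()
    _resolve_cache[id(ids)] = out
    return out[0], out[1]


def parse_structure(
    record: tuple[str, str, str],
    id1_set,
    id2_set,
    roi_prefixes: Iterable[str],
    min_insert: int = 20,
) -> StructuredRead:
    """Decompose a merged read into its structural fields.

    ``record`` is (read_id, sequence, quality string).  ``id1_set`` /
    ``id2_set`` may be plain sets of identifier sequences or mappings
    identifier -> (donor, treatment); with mappings, reads whose two
    identifiers disagree on donor or treatment are rejected (id_conflict).
    Rejected reads carry a ``reject_reason`` and are never silently dropped.
    """
    read_id, seq, qual = record
    if len(seq) != len(qual):
        raise ValueError(f"malformed record {read_id}: sequence/quality length mismatch")
    id1_ok, id1_map = _resolve_ids(id1_set)
    id2_ok, id2_map = _resolve_ids(id2_set)

    def rejected(reason: str) -> StructuredRead:
        n = len(seq)
        return StructuredRead(
            read_id,
            seq[:PRIMARY_BC_LEN],
            seq[PRIMARY_BC_LEN:HEAD_LEN],
            seq[HEAD_LEN : max(HEAD_LEN, n - TAIL_LEN)],
            qual[HEAD_LEN : max(HEAD_LEN, n - TAIL_LEN)],
            seq[n - TAIL_LEN : n - ID2_LEN] if n >= TAIL_LEN else "",
            seq[n - ID2_LEN :] if n >= TAIL_LEN else "",
            reject_reason=reason,
        )

    if len(seq) < HEAD_LEN + TAIL_LEN + min_insert:
        return rejected("too_short")
    pb = seq[:PRIMARY_BC_LEN]
    id1 = seq[PRIMARY_BC_LEN:HEAD_LEN]
    insert = seq[HEAD_LEN:-TAIL_LEN]
    iq = qual[HEAD_LEN:-TAIL_LEN]
    sb = seq[-TAIL_LEN:-ID2_LEN]
    id2 = seq[-ID2_LEN:]
    if id1 not in id1_ok:
        return rejected("id1")
    if id2 not in id2_ok:
        return rejected("id2")
    if not insert:
        return rejected("empty")
    if insert[:3] not in roi_prefixes and insert[:3] not in {p[:3] for p in roi_prefixes}:
        return rejected("prefix")
    donor = treatment = None
    if id1_map is not None and id2_map is not None:
        d1, t1 = id1_map[id1]
        d2, t2 = id2_map[id2]
        if (d1, t1) != (d2, t2):
            return rejected("id_conflict")
        donor, treatment = d1, t1
    elif id1_map is not None:
        donor, treatment = id1_map[id1]
    return StructuredRead(read_id, pb, id1, insert, iq, sb, id2, donor=donor, treatment=treatment)


def assign_gene(
    insert: str,
    discriminators: Mapping[str, tuple[tuple[int, int], str]],
    max_mismatch: int = 1,
    max_shift: int = 3,
) -> str:
    """Sort an insert to a gene on its discriminator hexamer.

    The hexamer interval (CDS coordinates, position 1 = first insert base)
    is tested at frame shifts of -max_shift..+max_shift against each gene's
    expected sequence with up to ``max_mismatch`` mismatches; the unique
    best match (fewest mismatches, then smallest |shift|) wins, ties and
    no-matches are unassigned.
    """
    # fast path: exact in-frame discriminator match for exactly one gene
    exact = None
    for gene, ((ds, de), hexamer) in discriminators.items():
        if insert[ds - 1 : de] == hexamer:
            if exact is not None:
                exact = None
                break
            exact = gene
    if exact is not None:
        return exact
    best: list[tuple[int, int, str]] = []
    for gene, ((ds, de), hexamer) in discriminators.items():
        width = de - ds + 1
        for shift in range(-max_shift, max_shift + 1):
            lo = ds - 1 + shift
            if lo < 0 or lo + width > len(insert):
                continue
            window = insert[lo : lo + width]
            mism = sum(a != b for a, b in zip(window, hexamer))
            if mism <= max_mismatch:
                best.append((mism, abs(shift), gene))
    if not best:
        return "unassigned"
    best.sort()
    top = [g for m, s, g in best if (m, s) == (best[0][0], best[0][1])]
    if len(set(top)) > 1:
        return "unassigned"
    return top[0]


def classify_spike_in(
    insert: str,
    spike_variants: Iterable[str] = DEFAULT_SPIKE_VARIANTS,
    site_span: tuple[int, int] = (16, 22),
) -> str:
    """Classify an insert as a resistant spike-in (recognition site replaced
    by a known heptamer) or genomic."""
    s, e = site_span
    occupied = insert[s - 1 : e]
    for variant in spike_variants:
        if occupied == variant:
            return f"spike_in:{variant}"
    return "genomic"


# --- banded affine-gap global alignment -------------------------------------

MATCH = 1
MISMATCH = -1
GAP_OPEN = -3  # charged on the first gapped base, extensions add GAP_EXTEND
GAP_EXTEND = -1
NEG = float("-inf")


def _banded_global_align(ref: str, query: str, band: int = 10) -> list[tuple[str, int, int]]:
    """Gotoh global alignment restricted to a diagonal band.

    Returns alignment ops as (op, ref_index, query_index) with 0-based
    indices; op is 'M' (match/mismatch), 'D' (ref base deleted from query)
    or 'I' (base inserted in query).
    """
    m, n = len(ref), len(query)
    width = band + abs(m - n)
    # dp[i][j]: best score aligning ref[:i] with query[:j]
    M = [dict() for _ in range(m + 1)]
    X = [dict() for _ in range(m + 1)]  # gap in query (deletion from ref)
    Y = [dict() for _ in range(m + 1)]  # gap in ref (insertion in query)
    M[0][0], X[0][0], Y[0][0] = 0.0, NEG, NEG
    for j in range(1, min(n, width) + 1):
        Y[0][j] = GAP_OPEN + GAP_EXTEND * (j - 1)
        M[0][j] = NEG
        X[0][j] = NEG
    for i in range(1, m + 1):
        jlo, jhi = max(0, i - width), min(n, i + width)
        for j in range(jlo, jhi + 1):
            if j == 0:
                X[i][0] = GAP_OPEN + GAP_EXTEND * (i - 1)
                M[i][0] = NEG
                Y[i][0] = NEG
                continue
            sub = MATCH if ref[i - 1] == query[j - 1] else MISMATCH
            prev = max(
                M[i - 1].get(j - 1, NEG), X[i - 1].get(j - 1, NEG), Y[i - 1].get(j - 1, NEG)
            )
            M[i][j] = prev + sub
            X[i][j] = max(
                max(M[i - 1].get(j, NEG), Y[i - 1].get(j, NEG)) + GAP_OPEN,
                X[i - 1].get(j, NEG) + GAP_EXTEND,
            )
            Y[i][j] = max(
                max(M[i].get(j - 1, NEG), X[i].get(j - 1, NEG)) + GAP_OPEN,
                Y[i].get(j - 1, NEG) + GAP_EXTEND,
            )
    # traceback from the best terminal layer
    i, j = m, n
    layer = max(("M", "X", "Y"), key=lambda L: {"M": M, "X": X, "Y": Y}[L][i].get(j, NEG))
    if {"M": M, "X": X, "Y": Y}[layer][i].get(j, NEG) == NEG:
        raise UnalignableRead("alignment fell outside the band")
    ops: list[tuple[str, int, int]] = []
    while i > 0 or j > 0:
        if layer == "M":
            sub = MATCH if ref[i - 1] == query[j - 1] else MISMATCH
            ops.append(("M", i - 1, j - 1))
            target = M[i][j] - sub
            i, j = i - 1, j - 1
            for L, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i].get(j, NEG) - target) < 1e-9:
                    layer = L
                    break
        elif layer == "X":
            ops.append(("D", i - 1, j))
            val = X[i][j]
            i -= 1
            if abs(X[i].get(j, NEG) + GAP_EXTEND - val) < 1e-9:
                layer = "X"
            elif abs(M[i].get(j, NEG) + GAP_OPEN - val) < 1e-9:
                layer = "M"
            else:
                layer = "Y"
        else:
            ops.append(("I", i, j - 1))
            val = Y[i][j]
            j -= 1
            if abs(Y[i].get(j, NEG) + GAP_EXTEND - val) < 1e-9:
                layer = "Y"
            elif abs(M[i].get(j, NEG) + GAP_OPEN - val) < 1e-9:
                layer = "M"
            else:
                layer = "X"
    ops.reverse()
    return ops


def align_and_call(
    insert: str,
    quals,
    roi: ROIModel,
    min_phred: int = 28,
    read_id: str = "",
    identity_floor: float = 0.8,
    band: int = 10,
    max_fast_mismatch: int = 6,
) -> list[ReadVariantObservation]:
    """Align an insert to the ROI reference and report variant observations.

    SNVs are reported only where the supporting base quality is >= min_phred;
    indels are left-normalized to their canonical representation.  A read
    whose alignment identity falls below ``identity_floor`` raises
    :class:`UnalignableRead` (treated as chimeric/unalignable upstream).
    Observations outside the recognition-site span are retained but flagged
    (``in_site=False``).

    ``quals`` may be a Phred+33 string or a sequence of integer scores.
    Equal-length inserts with few mismatches take a Hamming fast path; the
    banded affine-gap aligner handles everything else.
    """
    ref = roi.cds_sequence
    if isinstance(quals, str):
        qvals = None  # decode lazily, only at mismatch positions
        qstr = quals
    else:
        qvals = list(quals)
        qstr = None
    s, e = roi.site_span

    def q_at(j: int) -> int:
        return (ord(qstr[j]) - 33) if qvals is None else qvals[j]

    def snv_obs(ref_i: int, query_j: int) -> ReadVariantObservation | None:
        q = q_at(query_j)
        if q < min_phred:
            return None
        pos = ref_i + 1
        ev = MutationEvent("SNV", pos, pos, ref[ref_i], insert[query_j])
        return ReadVariantObservation(ev, q, read_id, s <= pos <= e)

    if len(insert) == len(ref):
        if insert == ref:
            return []
        diffs = [i for i, (a, b) in enumerate(zip(ref, insert)) if a != b]
        if len(diffs) <= max_fast_mismatch:
            obs = [snv_obs(i, i) for i in diffs]
            return [o for o in obs if o is not None]
    ops = _banded_global_align(ref, insert, band=band)
    matches = sum(1 for op, i, j in ops if op == "M" and ref[i] == insert[j])
    if matches / max(len(ref), len(insert)) < identity_floor:
        raise UnalignableRead(f"identity below {identity_floor}")
    observations: list[ReadVariantObservation] = []
    k = 0
    while k < len(ops):
        op, i, j = ops[k]
        if op == "M":
            if ref[i] != insert[j]:
                o = snv_obs(i, j)
                if o is not None:
                    observations.append(o)
            k += 1
        elif op == "D":
            start = i
            while k < len(ops) and ops[k][0] == "D":
                k += 1
            end = ops[k - 1][1]
            ev = refmodel.left_normalize_deletion(ref, start + 1, end + 1)
            in_site = ev.start <= e and ev.end >= s
            observations.append(ReadVariantObservation(ev, max(0, q_at(min(j, len(insert) - 1))), read_id, in_site))
        else:  # insertion run
            anchor = i  # inserted after ref position ``anchor`` (1-based: anchor)
            alt = []
            while k < len(ops) and ops[k][0] == "I":
                alt.append(insert[ops[k][2]])
                k += 1
            ev = MutationEvent("insertion", anchor, anchor, "", "".join(alt))
            in_site = s - 1 <= anchor <= e
            observations.append(ReadVariantObservation(ev, q_at(min(j, len(insert) - 1)), read_id, in_site))
    return observations


# --- FASTQ input and the per-read processing loop ---------------------------


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream (read_id, sequence, quality) from a FASTQ(.gz) file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper(), qual


def process_reads(
    records: Iterable[tuple[str, str, str]],
    rois: Mapping[str, ROIModel],
    id1_set,
    id2_set,
    spike_variants: Iterable[str] = DEFAULT_SPIKE_VARIANTS,
    min_phred: int = 28,
    trim_window: int = 3,
    trim_threshold: int = 30,
    min_insert: int = 20,
) -> tuple[list[StructuredRead], list[tuple[str, str]]]:
    """Run the full per-read stage: trim, parse, sort, classify, call.

    Returns (accepted StructuredReads with gene assignment and variant
    observations attached, rejected-read log as (read_id, reason) pairs).
    """
    discriminators = {g: roi.discriminator for g, roi in rois.items()}
    prefixes = {roi.cds_sequence[:3] for roi in rois.values()}
    accepted: list[StructuredRead] = []
    rejects: list[tuple[str, str]] = []
    ok_char = chr(33 + trim_threshold)  # reads whose min quality clears this skip trimming
    for read_id, seq, qual in records:
        if qual and min(qual) < ok_char:
            bases, quals = quality_trim(
                seq, [ord(c) - 33 for c in qual], window=trim_window, threshold=trim_threshold
            )
            seq, qual = bases, qual[: len(bases)]
        sr = parse_structure((read_id, seq, qual), id1_set, id2_set, prefixes, min_insert)
        if not sr.accepted:
            rejects.append((read_id, sr.reject_reason))
            continue
        gene = assign_gene(sr.insert, discriminators)
        if gene == "unassigned":
            rejects.append((read_id, "gene_unassigned"))
            sr.reject_reason = "gene_unassigned"
            continue
        sr.gene_assignment = gene
        spike = classify_spike_in(sr.insert, spike_variants, rois[gene].site_span)
        if spike != "genomic":
            sr.spike_variant = spike.split(":", 1)[1]
            accepted.append(sr)
            continue
        try:
            sr.observations = align_and_call(
                sr.insert, sr.quals, rois[gene], min_phred=min_phred, read_id=read_id
            )
        except UnalignableRead:
            rejects.append((read_id, "unalignable"))
            sr.reject_reason = "unalignable"
            continue
        accepted.append(sr)
    return accepted, rejects
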