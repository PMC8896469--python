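"""Reference model of the restriction-site region of interest (ROI).

The method targets a narrow window of the *HBB* / *HBD* coding sequence that
carries a Bsu36I recognition site (degenerate motif ``CCTNAGG`` at CDS
positions 16-22).  A mutation is *observable* when it abolishes the
recognition motif -- such molecules escape digestion and are enriched --
and when it does not belong to an excluded artifact class (coding-strand
C->A, G->A and G->T, i.e. barcoded-strand G->T, C->T and C->A changes that
reflect base damage rather than germline mutation).

Coordinates are 1-based CDS positions, position 1 = the A of ATG; intervals
are closed.  All sequences and mutation names are in coding-strand
orientation; the barcoded (antisense) strand enters only through the
complement mapping behind the artifact-class policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

__all__ = [
    "IUPAC",
    "MutationEvent",
    "ArtifactClassPolicy",
    "ROIModel",
    "find_site",
    "apply_mutation",
    "left_normalize_deletion",
    "is_observable",
    "enumerate_observable_point_mutations",
    "enumerate_observable_deletions",
    "name_mutation",
    "mutation_table",
    "hbb_roi",
    "hbd_roi",
]

#: IUPAC nucleotide codes -> matching base sets.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

NUCLEOTIDES = "ACGT"

# First 18 codons of the human HBB / HBD coding sequences.  Both carry the
# Bsu36I site CCTGAGG at CDS 16-22; they differ in the discriminator hexamer
# at CDS 33-38 (CGTTAC for HBB, TGTCAA for HBD), which is what gene sorting
# keys on.
HBB_CDS_5PRIME = "ATGGTGCATCTGACTCCTGAGGAGAAGTCTGCCGTTACTGCCCTGTGGGGCAAG"
HBD_CDS_5PRIME = "ATGGTGCATCTGACTCCTGAGGAGAAGACTGCTGTCAATGCCCTGTGGGGCAAG"


def _check_nucleotides(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"non-nucleotide characters in {what}: {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class MutationEvent:
    """A canonical mutation on the coding strand.

    ``start``/``end`` are 1-based closed CDS coordinates.  SNVs have
    ``start == end``; deletions are left-normalized over repeats so that
    equivalent representations (identical product sequence) share one
    canonical event.  Insertions place ``alt`` after position ``start``.
    """

    kind: str  # "SNV" | "deletion" | "insertion"
    start: int
    end: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.kind not in ("SNV", "deletion", "insertion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.kind == "SNV":
            if self.start != self.end or len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("SNV must span a single position")
            if self.ref == self.alt:
                raise ValueError("SNV ref must differ from alt")
        if self.kind == "deletion":
            if self.end - self.start + 1 != len(self.ref) or self.alt != "":
                raise ValueError("deletion interval must match ref; alt must be empty")
        if self.kind == "insertion" and (self.ref != "" or not self.alt):
            raise ValueError("insertion must have empty ref and nonempty alt")

    @property
    def name(self) -> str:
        return name_mutation(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def snv(pos: int, ref: str, alt: str) -> MutationEvent:
    """Shorthand constructor for an SNV event."""
    return MutationEvent("SNV", pos, pos, ref, alt)


@dataclass(frozen=True)
class ArtifactClassPolicy:
    """SNV classes excluded from rate estimation, in coding-strand terms.

    The default excludes coding-strand C->A and G->A (complements of the
    barcoded-strand G->T and C->T damage classes) plus coding-strand G->T
    (the complement of barcoded-strand C->A, excluded for its association
    with guanine oxidation).
    """

    excluded_snv_classes_coding_strand: frozenset[tuple[str, str]] = frozenset(
        {("C", "A"), ("G", "A"), ("G", "T")}
    )

    @classmethod
    def from_barcoded_strand(cls, classes: Iterable[tuple[str, str]]) -> "ArtifactClassPolicy":
        """Build the policy from barcoded-strand (antisense) change classes."""
        mapped = frozenset(
            (r.translate(_COMPLEMENT), a.translate(_COMPLEMENT)) for r, a in classes
        )
        return cls(mapped)

    @classmethod
    def none(cls) -> "ArtifactClassPolicy":
        return cls(frozenset())

    def is_excluded(self, event: MutationEvent) -> bool:
        if event.kind != "SNV":
            return False
        return (event.ref, event.alt) in self.excluded_snv_classes_coding_strand


#: Barcoded-strand damage classes behind the default policy.
DEFAULT_BARCODED_STRAND_CLASSES = (("G", "T"), ("C", "T"), ("C", "A"))


@dataclass(frozen=True)
class ROIModel:
    """The ROI reference: coding-strand sequence plus site geometry."""

    gene_id: str
    cds_sequence: str
    site_span: tuple[int, int] = (16, 22)
    recognition: str = "CCTNAGG"
    discriminator: tuple[tuple[int, int], str] = ((33, 38), "CGTTAC")

    def __post_init__(self) -> None:
        _check_nucleotides(self.cds_sequence, "cds_sequence")
        s, e = self.site_span
        if e - s + 1 != len(self.recognition):
            raise ValueError("site_span length must equal recognition length")
        if not _motif_matches_at(self.cds_sequence, self.recognition, s):
            raise ValueError(
                f"recognition {self.recognition} does not match cds_sequence at {self.site_span}"
            )
        (ds, de), hexamer = self.discriminator
        if self.cds_sequence[ds - 1 : de] != hexamer:
            raise ValueError("discriminator hexamer does not match its interval")

    @property
    def site_sequence(self) -> str:
        s, e = self.site_span
        return self.cds_sequence[s - 1 : e]

    def site_positions(self) -> range:
        return range(self.site_span[0], self.site_span[1] + 1)

    @classmethod
    def from_fasta(cls, path, gene_id: str, **kwargs) -> "ROIModel":
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id == gene_id:
                return cls(gene_id=gene_id, cds_sequence=str(rec.seq).upper(), **kwargs)
        raise ValueError(f"record {gene_id!r} not found in {path}")


def hbb_roi() -> ROIModel:
    return ROIModel("HBB", HBB_CDS_5PRIME)


def hbd_roi() -> ROIModel:
    return ROIModel("HBD", HBD_CDS_5PRIME, discriminator=((33, 38), "TGTCAA"))


def _motif_matches_at(seq: str, motif: str, pos: int) -> bool:
    """Does ``motif`` (IUPAC) match ``seq`` at 1-based offset ``pos``?"""
    if pos < 1 or pos + len(motif) - 1 > len(seq):
        return False
    return all(seq[pos - 1 + i] in IUPAC[m] for i, m in enumerate(motif))


def find_site(sequence: str, recognition: str) -> list[int]:
    """All 1-based offsets where the IUPAC motif matches the sequence."""
    _check_nucleotides(sequence)
    bad = set(recognition) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC codes in motif: {sorted(bad)}")
    L = len(recognition)
    return [
        pos for pos in range(1, len(sequence) - L + 2)
        if _motif_matches_at(sequence, recognition, pos)
    ]


def apply_mutation(seq: str, event: MutationEvent) -> str:
    """Product sequence after applying ``event`` to ``seq`` (1-based coords)."""
    if event.kind == "SNV":
        p = event.start
        if not 1 <= p <= len(seq):
            raise ValueError(f"SNV position {p} outside sequence of length {len(seq)}")
        if seq[p - 1] != event.ref:
            raise ValueError(f"ref mismatch at {p}: sequence has {seq[p-1]}, event says {event.ref}")
        return seq[: p - 1] + event.alt + seq[p:]
    if event.kind == "deletion":
        s, e = event.start, event.end
        if not (1 <= s <= e <= len(seq)):
            raise ValueError(f"deletion {s}_{e} outside sequence of length {len(seq)}")
        if seq[s - 1 : e] != event.ref:
            raise ValueError(f"ref mismatch for deletion {s}_{e}")
        return seq[: s - 1] + seq[e:]
    # insertion: alt goes after position start (start may be 0 for a 5' insertion)
    s = event.start
    if not 0 <= s <= len(seq):
        raise ValueError(f"insertion anchor {s} outside sequence")
    return seq[:s] + event.alt + seq[s:]


def left_normalize_deletion(seq: str, start: int, end: int) -> MutationEvent:
    """Canonical (leftmost) representation of deleting ``seq[start..end]``.

    Shifting left by one is valid whenever the base preceding the interval
    equals its last base -- both representations delete the same repeat unit
    and yield an identical product.
    """
    if not (1 <= start <= end <= len(seq)):
        raise ValueError("deletion interval outside sequence")
    while start > 1 and seq[start - 2] == seq[end - 1]:
        start -= 1
        end -= 1
    return MutationEvent("deletion", start, end, seq[start - 1 : end], "")


def _product_site_window(event: MutationEvent, site_span: tuple[int, int], motif_len: int) -> tuple[int, int]:
    """Interval of product coordinates treated as the original site locale."""
    s, e = site_span
    delta = len(event.alt) - len(event.ref)
    lo = s if s < event.start else max(1, s + delta)
    hi = e + delta if e >= event.start else e
    return lo, hi


def is_observable(
    mutation: MutationEvent,
    roi: ROIModel,
    policy: ArtifactClassPolicy | None = None,
) -> bool:
    """True iff the mutation abolishes the recognition motif at the site
    locale of the product sequence and is not artifact-class excluded.

    Re-formed sites are caught: the product is rescanned in a window of
    +/- one motif length around the (coordinate-mapped) site locale, so a
    deletion whose junction recreates the motif (e.g. removing CDS 15-16
    of the study ROI, product ``...ACCTGAGG...``) is correctly classified
    as not observable.
    """
    if policy is None:
        policy = ArtifactClassPolicy()
    if mutation.end < 1 or mutation.start > len(roi.cds_sequence):
        raise ValueError("mutation outside the modeled sequence")
    if policy.is_excluded(mutation):
        return False
    product = apply_mutation(roi.cds_sequence, mutation)
    L = len(roi.recognition)
    lo, hi = _product_site_window(mutation, roi.site_span, L)
    scan_lo = max(1, lo - L)
    scan_hi = min(len(product), hi + L)
    for pos in range(scan_lo, scan_hi - L + 2):
        if _motif_matches_at(product, roi.recognition, pos):
            # a motif match overlapping the locale -> still cleavable
            if pos <= hi and pos + L - 1 >= lo:
                return False
    return True


def enumerate_observable_point_mutations(
    roi: ROIModel, policy: ArtifactClassPolicy | None = None
) -> set[MutationEvent]:
    """All observable SNVs within the recognition-site span.

    For the study ROIs under the default policy this set has 12 members over
    the 6 informative positions (the degenerate N position contributes none).
    """
    if policy is None:
        policy = ArtifactClassPolicy()
    out: set[MutationEvent] = set()
    for pos in roi.site_positions():
        ref = roi.cds_sequence[pos - 1]
        for alt in NUCLEOTIDES:
            if alt == ref:
                continue
            ev = snv(pos, ref, alt)
            if is_observable(ev, roi, policy):
                out.add(ev)
    return out


def enumerate_observable_deletions(
    roi: ROIModel, max_len: int = 3
) -> tuple[set[MutationEvent], int]:
    """Observable deletions of 1..max_len bases removing >=1 site base.

    Returns ``(canonical_events, positional_count)``: the set deduplicated
    by resulting product sequence (named by the leftmost representation)
    and the count of positional, non-deduplicated representations.  Both
    conventions are reported because neither is privileged a priori.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    seq = roi.cds_sequence
    s, e = roi.site_span
    by_product: dict[str, MutationEvent] = {}
    positional = 0
    for length in range(1, max_len + 1):
        for start in range(max(1, s - length + 1), e + 1):
            end = start + length - 1
            if end > len(seq):
                continue
            ev = MutationEvent("deletion", start, end, seq[start - 1 : end], "")
            if not is_observable(ev, roi):
                continue
            positional += 1
            product = apply_mutation(seq, ev)
            canon = left_normalize_deletion(seq, start, end)
            prev = by_product.get(product)
            if prev is None or (canon.start, canon.end) < (prev.start, prev.end):
                by_product[product] = canon
    return set(by_product.values()), positional


def name_mutation(mutation: MutationEvent) -> str:
    """Canonical name: SNVs ``<pos><ref>-><alt>`` (arrow U+2192), deletions
    ``<pos>del<base>`` / ``<start>_<end>del<bases>``, insertions
    ``<pos>_<pos+1>ins<bases>``."""
    if mutation.kind == "SNV":
        return f"{mutation.start}{mutation.ref}→{mutation.alt}"
    if mutation.kind == "deletion":
        if mutation.start == mutation.end:
            return f"{mutation.start}del{mutation.ref}"
        return f"{mutation.start}_{mutation.end}del{mutation.ref}"
    return f"{mutation.start}_{mutation.start + 1}ins{mutation.alt}"


def mutation_table(
    events: Iterable[MutationEvent],
    roi: ROIModel | None = None,
    policy: ArtifactClassPolicy | None = None,
) -> pd.DataFrame:
    """Tabulate events (TSV-ready): name/kind/start/end/ref/alt/observable/artifact_class."""
    if policy is None:
        policy = ArtifactClassPolicy()
    rows = []
    for ev in sorted(events):
        rows.append(
            {
                "name": ev.name,
                "kind": ev.kind,
                "start": ev.start,
                "end": ev.end,
                "ref": ev.ref,
                "alt": ev.alt,
                "observable": bool(is_observable(ev, roi, policy)) if roi is not None else None,
                "artifact_class": policy.is_excluded(ev),
            }
        )
    return pd.DataFrame(
        rows, columns=["name", "kind", "start", "end", "ref", "alt", "observable", "artifact_class"]
    )
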