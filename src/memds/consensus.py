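"""Barcode-family grouping and per-molecule consensus calling.

Reads sharing a primary barcode (within one donor, treatment and gene) form
a *family* descending from a single original molecule.  Sporadic errors from
sequencing or from any amplification step after the first linear copies are
unlikely to recur across copies and are suppressed by requiring each
consensus mutation to appear in reads from distinct linear-amplification
events (distinct secondary barcodes) and in a large fraction of the family.

Families that are too shallow to confirm anything are discarded; families
showing two well-supported conflicting alleles at one position are flagged
as primary-barcode collisions (``ambiguous``) and excluded from molecule
counts -- conservative, and rare at 14-nt barcode diversity.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .refmodel import ArtifactClassPolicy, MutationEvent, ROIModel, find_site
from .readproc import StructuredRead

__all__ = [
    "ReadFamily",
    "ConsensusCall",
    "group_families",
    "call_consensus",
    "apply_artifact_policy",
    "count_molecules",
    "consensus_table",
    "MoleculeCounts",
]

FamilyKey = tuple  # (donor, treatment, gene, primary_barcode)


@dataclass(slots=True)
class ReadFamily:
    key: FamilyKey
    reads: list[StructuredRead] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.reads)

    @property
    def distinct_secondary_count(self) -> int:
        return len({r.secondary_barcode for r in self.reads})


@dataclass(slots=True)
class MutationSupport:
    mutation: MutationEvent
    reads: int
    distinct_secondary: int


@dataclass(slots=True)
class ConsensusCall:
    key: FamilyKey
    status: str  # "WT" | "mutant" | "spike_in:<variant>" | "ambiguous" | "discarded:<reason>"
    mutations: list[MutationSupport]
    depth: int
    distinct_secondary: int
    excluded_mutations: list[MutationSupport] = field(default_factory=list)

    @property
    def donor(self):
        return self.key[0]

    @property
    def treatment(self):
        return self.key[1]

    @property
    def gene(self):
        return self.key[2]


def group_families(reads: Iterable[StructuredRead]) -> list[ReadFamily]:
    """Partition accepted reads by (donor, treatment, gene, primary barcode).

    Ordering is lexicographic by key, so the result is independent of the
    input read order.
    """
    buckets: dict[FamilyKey, list[StructuredRead]] = defaultdict(list)
    for r in reads:
        if r.reject_reason is not None:
            continue
        key = (r.donor, r.treatment, r.gene_assignment, r.primary_barcode)
        buckets[key].append(r)
    return [
        ReadFamily(key, sorted(rs, key=lambda r: (r.secondary_barcode, r.read_id)))
        for key, rs in sorted(buckets.items(), key=lambda kv: tuple(map(str, kv[0])))
    ]


def call_consensus(
    family: ReadFamily,
    min_reads: int = 3,
    min_distinct_secondary: int = 2,
    min_support_fraction: float = 0.8,
) -> ConsensusCall:
    """Call one consensus molecule from a read family.

    A mutation is confirmed iff it is observed in at least
    ``min_distinct_secondary`` reads carrying distinct secondary barcodes
    and in at least ``min_support_fraction`` of the family's reads covering
    its position.  Families below the depth/diversity floor are discarded;
    spike-in families are labelled by their variant and report no genomic
    mutations; well-supported conflicting alleles at one position mean two
    molecules collided on one primary barcode (``ambiguous``).
    """
    if not family.reads:
        raise ValueError("empty family")
    depth = family.depth
    distinct = family.distinct_secondary_count
    if depth < min_reads or distinct < min_distinct_secondary:
        return ConsensusCall(family.key, "discarded:insufficient", [], depth, distinct)

    spike_sec: dict[str | None, set[str]] = defaultdict(set)
    for r in family.reads:
        spike_sec[r.spike_variant].add(r.secondary_barcode)
    supported = [
        v for v, secs in spike_sec.items() if len(secs) >= min_distinct_secondary
    ]
    spike_supported = [v for v in supported if v is not None]
    if spike_supported:
        if len(spike_supported) > 1 or None in supported:
            # two well-supported origins under one primary barcode: collision
            return ConsensusCall(family.key, "ambiguous", [], depth, distinct)
        # sporadically discordant reads (sequencing errors in the replaced
        # heptamer) do not outvote a well-supported spike-in
        return ConsensusCall(family.key, f"spike_in:{spike_supported[0]}", [], depth, distinct)

    support: dict[MutationEvent, set[str]] = defaultdict(set)
    read_count: Counter = Counter()
    for r in family.reads:
        for obs in r.observations:
            support[obs.mutation].add(r.secondary_barcode)
            read_count[obs.mutation] += 1

    confirmed: list[MutationSupport] = []
    for mut, secondaries in support.items():
        # every read in the family covers the full short insert, so the
        # covering-read denominator is the family depth
        if len(secondaries) >= min_distinct_secondary and read_count[mut] >= min_support_fraction * depth:
            confirmed.append(MutationSupport(mut, read_count[mut], len(secondaries)))
    confirmed.sort(key=lambda ms: (ms.mutation.start, ms.mutation.kind, ms.mutation.alt))

    by_position: dict[tuple, list[MutationSupport]] = defaultdict(list)
    for ms in confirmed:
        by_position[(ms.mutation.kind, ms.mutation.start)].append(ms)
    if any(len(v) > 1 for v in by_position.values()):
        return ConsensusCall(family.key, "ambiguous", confirmed, depth, distinct)

    status = "mutant" if confirmed else "WT"
    return ConsensusCall(family.key, status, confirmed, depth, distinct)


def apply_artifact_policy(call: ConsensusCall, policy: ArtifactClassPolicy) -> ConsensusCall:
    """Strip excluded-class SNVs from a consensus call (kept in a side log).

    A family whose only mutations were artifact-class reverts to WT for
    counting purposes.
    """
    if call.status != "mutant":
        return call
    kept = [ms for ms in call.mutations if not policy.is_excluded(ms.mutation)]
    dropped = [ms for ms in call.mutations if policy.is_excluded(ms.mutation)]
    status = "mutant" if kept else "WT"
    return ConsensusCall(
        call.key, status, kept, call.depth, call.distinct_secondary,
        excluded_mutations=call.excluded_mutations + dropped,
    )


@dataclass
class MoleculeCounts:
    """Per-(donor, treatment, gene) molecule tallies.

    W: wild-type genomic molecules; M: molecules per confirmed mutation;
    S: sensitive molecules (genomic consensus retaining the recognition
    motif at the site locale); R: resistant spike-in molecules per variant.
    """

    W: int = 0
    M: Counter = field(default_factory=Counter)
    S: int = 0
    R: Counter = field(default_factory=Counter)
    families: int = 0
    ambiguous: int = 0
    discarded: int = 0

    @property
    def mutant_molecules(self) -> int:
        return int(sum(self.M.values()))


def _retains_site(call: ConsensusCall, roi: ROIModel) -> bool:
    """Does the consensus molecule still carry the recognition motif?"""
    from .refmodel import apply_mutation

    seq = roi.cds_sequence
    s, e = roi.site_span
    # apply confirmed mutations right-to-left so coordinates stay valid
    for ms in sorted(call.mutations, key=lambda m: -m.mutation.start):
        try:
            seq = apply_mutation(seq, ms.mutation)
        except ValueError:
            return False
    L = len(roi.recognition)
    for pos in find_site(seq, roi.recognition):
        if pos <= e + L and pos + L - 1 >= max(1, s - L):
            return True
    return False


def count_molecules(
    calls: Iterable[ConsensusCall],
    rois: Mapping[str, ROIModel] | None = None,
) -> dict[tuple, MoleculeCounts]:
    """Tally consensus calls into per-(donor, treatment, gene) molecule counts.

    Each non-discarded, non-ambiguous family contributes exactly one
    molecule.  When ``rois`` is given, S counts genomic molecules whose
    consensus retains the recognition motif (digestible at the next round);
    without it, S = W + mutants that carry no site-disrupting call, which is
    exact for SNV-only data but approximate for re-formed sites.
    """
    out: dict[tuple, MoleculeCounts] = defaultdict(MoleculeCounts)
    for call in calls:
        donor, treatment, gene = call.key[0], call.key[1], call.key[2]
        mc = out[(donor, treatment, gene)]
        mc.families += 1
        if call.status.startswith("discarded"):
            mc.discarded += 1
            continue
        if call.status == "ambiguous":
            mc.ambiguous += 1
            continue
        if call.status.startswith("spike_in:"):
            mc.R[call.status.split(":", 1)[1]] += 1
            continue
        if call.status == "WT":
            mc.W += 1
            mc.S += 1
            continue
        for ms in call.mutations:
            mc.M[ms.mutation.name] += 1
        if rois is not None and gene in rois:
            if _retains_site(call, rois[gene]):
                mc.S += 1
    return dict(out)


def consensus_table(calls: Iterable[ConsensusCall]) -> pd.DataFrame:
    """Flat consensus table (TSV-ready)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "donor": c.key[0],
                "treatment": c.key[1],
                "gene": c.key[2],
                "barcode": c.key[3],
                "status": c.status,
                "depth": c.depth,
                "distinct_secondary": c.distinct_secondary,
                "mutations": ";".join(ms.mutation.name for ms in c.mutations),
                "excluded": ";".join(ms.mutation.name for ms in c.excluded_mutations),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "donor", "treatment", "gene", "barcode", "status",
            "depth", "distinct_secondary", "mutations", "excluded",
        ],
    )
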