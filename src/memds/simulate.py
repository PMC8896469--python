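"""Ground-truthed synthetic experiments: molecules -> digestion -> barcoding
-> linear amplification -> sequencing, emitting merged reads plus truth
tables so every downstream stage is testable end to end.

The generator mirrors the experimental design: per-donor pools of genomic
molecules acquire target mutations at configured per-molecule rates; the
treated mixture is digested (site-bearing molecules survive with probability
``digestion_survival`` = 1/E*, motif-destroying mutants and resistant
spike-ins always survive); the untreated mixture carries ``f_D`` of the DNA
and ``f_S`` times the spike volume and skips digestion.  Barcoding then
draws a unique random 14-nt primary barcode per molecule and a Poisson
number of linearly amplified copies, each with its own random 5-nt
secondary barcode; ~65% of molecules are lost before amplification.
Per-copy polymerase errors and per-base sequencing errors use a uniform
error model with a flat Phred score -- deliberately pessimistic, since
miscalled bases are *not* flagged by low quality and must be removed by the
family-consensus rule alone.  Strand-aware damage artifacts (barcoded-strand
G->T / C->T, i.e. coding-strand C->A / G->A) are injected at the molecule
level, so they recur across all copies exactly like the real artifact class.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .refmodel import MutationEvent, ROIModel, apply_mutation, hbb_roi, hbd_roi
from .readproc import HEAD_LEN, TAIL_LEN

__all__ = ["SimConfig", "simulate_molecules", "simulate_reads", "simulate_called_counts",
           "recovery_report", "write_fastq", "default_identifiers"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# identifier pool: 4-mers at pairwise Hamming distance >= 2
_ID_POOL = [
    "AACC", "AGGT", "ACTG", "ATGA", "CATT", "CCGA", "CGAC", "CTCG",
    "GAAG", "GCTA", "GGCC", "GTGT", "TAGC", "TCAA", "TGTC", "TTAG",
]


def default_identifiers(donors, treatments=("treated", "untreated")) -> dict:
    """Assign a unique (ID-1, ID-2) pair per (donor, treatment)."""
    out = {}
    i = 0
    for d in donors:
        for t in treatments:
            if i >= len(_ID_POOL):
                raise ValueError("identifier pool exhausted; supply identifiers explicitly")
            out[(d, t)] = (_ID_POOL[i], _ID_POOL[i])
            i += 1
    return out


@dataclass
class SimConfig:
    """Study conditions for a synthetic experiment.

    Defaults follow the real protocol's regime: 7e7 cells per donor
    (60-80 million sperm genomes), ~65% material loss before amplification,
    a 1:120 untreated mix (5% of the DNA, 6x the spike volume) and mean
    family size 5.  Desk-scale work shrinks ``cells_per_donor`` to 1e5-1e6
    and raises mutation rates to 1e-5-1e-4 so expected event counts stay in
    the real experiment's single-digit regime at laptop cost.
    """

    rois: Mapping[str, ROIModel] = field(default_factory=lambda: {"HBB": hbb_roi(), "HBD": hbd_roi()})
    donors: tuple = ("D1",)
    cells_per_donor: int = 70_000_000
    mutation_rates: Mapping[str, Mapping[MutationEvent, float]] = field(default_factory=dict)
    digestion_survival: float = 1e-5  # phi; true enrichment factor E* = 1/phi
    material_loss: float = 0.65
    spike_in_per_variant: int = 1000  # treated-mixture molecules per resistant variant
    spike_variants: tuple = ("TTATGTT", "ACGAGAC")
    dna_fraction_untreated: float = 0.05  # f_D
    spike_factor_untreated: float = 6.0  # f_S
    family_size_mean: float = 5.0
    polymerase_error_rate: float = 1e-5  # per base per copy
    seq_error_rate: float = 1e-3  # per base per read
    phred_score: int = 37  # flat quality; errors are NOT downgraded
    damage_ca_rate: float = 0.0  # coding C->A (barcoded-strand G->T) per eligible base per molecule
    damage_ga_rate: float = 0.0  # coding G->A (barcoded-strand C->T)
    identifiers: Mapping | None = None  # (donor, treatment) -> (id1, id2)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.digestion_survival, self.material_loss, self.seq_error_rate,
                  self.polymerase_error_rate, self.damage_ca_rate, self.damage_ga_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.identifiers is None:
            self.identifiers = default_identifiers(self.donors)

    def gene_rates(self, gene: str) -> Mapping[MutationEvent, float]:
        return self.mutation_rates.get(gene, {})


def _mutant_insert(roi: ROIModel, event: MutationEvent) -> str:
    return apply_mutation(roi.cds_sequence, event)


def _spike_insert(roi: ROIModel, variant: str) -> str:
    s, e = roi.site_span
    return roi.cds_sequence[: s - 1] + variant + roi.cds_sequence[e:]


def _destroys_site(roi: ROIModel, event: MutationEvent) -> bool:
    from .refmodel import ArtifactClassPolicy, is_observable

    # observability minus the artifact-policy veto: what matters for
    # digestion is only whether the motif survives
    return is_observable(event, roi, ArtifactClassPolicy.none())


def simulate_molecules(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Draw the molecule-level truth table for both libraries.

    One row per molecule entering the barcoding reaction: donor, gene,
    library (treated/untreated), haplotype ("WT", a mutation name, or
    "spike:<variant>"), is_spike_in, survives_digestion.  Wild-type and
    non-protected mutants of the treated library appear only if they
    survived digestion; the untreated library is scaled by f_D (DNA) and
    f_S (spike volume) and skips digestion entirely.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    # blocks of identical molecules: (count, donor, gene, library, haplotype, is_spike)
    blocks: list[tuple[int, str, str, str, str, bool]] = []
    f_D, f_S = cfg.dna_fraction_untreated, cfg.spike_factor_untreated
    for donor in cfg.donors:
        for gene, roi in cfg.rois.items():
            rates = cfg.gene_rates(gene)
            events = list(rates)
            protected = {ev: _destroys_site(roi, ev) for ev in events}
            for library, dna_scale, spike_scale, digested in (
                ("treated", 1.0, 1.0, True),
                ("untreated", f_D, f_S, False),
            ):
                cells = cfg.cells_per_donor * dna_scale
                n_mut = {ev: rng.poisson(cells * rates[ev]) for ev in events}
                n_wt = max(0, int(round(cells)) - sum(n_mut.values()))
                if digested:
                    n_wt = int(rng.binomial(n_wt, cfg.digestion_survival))
                    n_mut = {
                        ev: (n if protected[ev] else int(rng.binomial(n, cfg.digestion_survival)))
                        for ev, n in n_mut.items()
                    }
                blocks.append((n_wt, donor, gene, library, "WT", False))
                for ev, n in n_mut.items():
                    blocks.append((n, donor, gene, library, ev.name, False))
                for variant in cfg.spike_variants:
                    n_spike = int(round(cfg.spike_in_per_variant * spike_scale))
                    blocks.append((n_spike, donor, gene, library, f"spike:{variant}", True))
    counts = np.array([b[0] for b in blocks])
    df = pd.DataFrame(
        {
            "molecule_id": np.arange(int(counts.sum())),
            "donor": np.repeat([b[1] for b in blocks], counts),
            "gene": np.repeat([b[2] for b in blocks], counts),
            "library": np.repeat([b[3] for b in blocks], counts),
            "haplotype": np.repeat([b[4] for b in blocks], counts),
            "is_spike_in": np.repeat([b[5] for b in blocks], counts),
        }
    )
    # every listed molecule is in the post-digestion pool by construction
    df["survives_digestion"] = True
    return df


def _random_kmers(rng, n: int, k: int) -> list[str]:
    arr = _BASES[rng.integers(0, 4, size=(n, k))]
    return [bytes(row).decode() for row in arr]


def _apply_damage(insert: str, rng, cfg: SimConfig) -> tuple[str, list[str]]:
    """Molecule-level damage: coding C->A and G->A at configured per-base rates."""
    if cfg.damage_ca_rate == 0 and cfg.damage_ga_rate == 0:
        return insert, []
    names = []
    seq = list(insert)
    for i, b in enumerate(seq):
        if b == "C" and rng.random() < cfg.damage_ca_rate:
            seq[i] = "A"
            names.append(f"{i + 1}C→A")
        elif b == "G" and rng.random() < cfg.damage_ga_rate:
            seq[i] = "A"
            names.append(f"{i + 1}G→A")
    return "".join(seq), names


def simulate_reads(
    truth: pd.DataFrame, cfg: SimConfig, rng=None
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Amplify and sequence the molecule table into merged reads.

    Returns (records, molecule_fate): records are (read_id, sequence,
    quality) tuples with the full read layout; molecule_fate extends the
    truth table with the per-molecule loss/depth outcome (``n_reads`` = 0
    for molecules lost to material loss or drawing zero copies) and any
    injected damage.  Determinism: a fixed config seed yields a byte-
    identical read stream.
    """
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    n_mol = len(truth)
    survive_loss = rng.random(n_mol) >= cfg.material_loss
    depths = np.where(survive_loss, rng.poisson(cfg.family_size_mean, n_mol), 0)
    primaries = _random_kmers(rng, n_mol, 14)
    insert_cache: dict[tuple[str, str], str] = {}

    def base_insert(gene: str, haplotype: str) -> str:
        key = (gene, haplotype)
        if key not in insert_cache:
            roi = cfg.rois[gene]
            if haplotype == "WT":
                insert_cache[key] = roi.cds_sequence
            elif haplotype.startswith("spike:"):
                insert_cache[key] = _spike_insert(roi, haplotype.split(":", 1)[1])
            else:
                ev = _event_from_name(roi, haplotype)
                insert_cache[key] = apply_mutation(roi.cds_sequence, ev)
        return insert_cache[key]

    records: list[tuple[str, str, str]] = []
    damage_col = []
    qchar = chr(33 + cfg.phred_score)
    py_rng = np.random.default_rng(rng.integers(2**31))
    donors = truth["donor"].to_numpy()
    genes = truth["gene"].to_numpy()
    libs = truth["library"].to_numpy()
    haps = truth["haplotype"].to_numpy()
    mol_ids = truth["molecule_id"].to_numpy()
    read_no = 0
    for idx in range(n_mol):
        k = int(depths[idx])
        if k == 0:
            damage_col.append("")
            continue
        insert, damage = _apply_damage(base_insert(genes[idx], haps[idx]), py_rng, cfg)
        damage_col.append(";".join(damage))
        id1, id2 = cfg.identifiers[(donors[idx], libs[idx])]
        secondaries = _random_kmers(py_rng, k, 5)
        L = len(insert)
        qual = qchar * (HEAD_LEN + L + TAIL_LEN)
        for c in range(k):
            seq_ins = insert
            # polymerase errors: on this copy's template, insert region only
            n_pol = py_rng.binomial(L, cfg.polymerase_error_rate) if cfg.polymerase_error_rate else 0
            if n_pol:
                seq_ins = _mutate(seq_ins, py_rng, n_pol)
            read = primaries[idx] + id1 + seq_ins + secondaries[c] + id2
            n_err = py_rng.binomial(len(read), cfg.seq_error_rate) if cfg.seq_error_rate else 0
            if n_err:
                read = _mutate(read, py_rng, n_err)
            records.append((f"r{read_no}|m{mol_ids[idx]}", read, qual))
            read_no += 1
    fate = truth.copy()
    fate["n_reads"] = depths
    fate["damage"] = damage_col
    return records, fate


def _event_from_name(roi: ROIModel, name: str) -> MutationEvent:
    """Parse a canonical mutation name back into an event (inverse of
    name_mutation for SNVs and deletions)."""
    if "→" in name and "del" not in name and "ins" not in name:
        left, alt = name.split("→")
        pos, ref = int(left[:-1]), left[-1]
        return MutationEvent("SNV", pos, pos, ref, alt)
    if "del" in name:
        coords, bases = name.split("del")
        if "_" in coords:
            s, e = map(int, coords.split("_"))
        else:
            s = e = int(coords)
        return MutationEvent("deletion", s, e, bases, "")
    if "ins" in name:
        coords, bases = name.split("ins")
        s = int(coords.split("_")[0])
        return MutationEvent("insertion", s, s, "", bases)
    raise ValueError(f"cannot parse mutation name {name!r}")


def _mutate(seq: str, rng, n_errors: int) -> str:
    b = bytearray(seq, "ascii")
    for pos in rng.integers(0, len(b), size=n_errors):
        cur = b[pos]
        choices = [x for x in b"ACGT" if x != cur]
        b[pos] = choices[int(rng.integers(0, 3))]
    return b.decode()


def write_fastq(records, path) -> Path:
    """Write (read_id, seq, qual) records as FASTQ(.gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path


def simulate_called_counts(cfg: SimConfig, rng=None) -> dict:
    """Molecule-level fast path: the called-molecule tallies a perfect
    consensus stage would produce, skipping read synthesis.

    Each molecule survives material loss independently and is *called* when
    its family has at least 3 reads (Poisson family sizes; secondary-barcode
    diversity is not limiting at these depths).  Returns per
    (donor, treatment, gene) dicts with W, M (per mutation), S, R (per
    variant) -- the same shape consensus.count_molecules produces.  Used by
    calibration experiments (enrichment recovery, CI coverage) where read-
    level error processes are irrelevant and desk time matters.
    """
    from scipy.stats import poisson

    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    truth = simulate_molecules(cfg, rng)
    p_called = (1 - cfg.material_loss) * float(1 - poisson.cdf(2, cfg.family_size_mean))
    out: dict = {}
    grouped = truth.groupby(["donor", "library", "gene", "haplotype"], sort=True).size()
    for (donor, library, gene, hap), n in grouped.items():
        key = (donor, library, gene)
        rec = out.setdefault(key, {"W": 0, "M": {}, "S": 0, "R": {}})
        called = int(rng.binomial(int(n), p_called))
        if hap == "WT":
            rec["W"] += called
            rec["S"] += called
        elif hap.startswith("spike:"):
            rec["R"][hap.split(":", 1)[1]] = rec["R"].get(hap.split(":", 1)[1], 0) + called
        else:
            rec["M"][hap] = rec["M"].get(hap, 0) + called
    return out


def recovery_report(
    estimates: Mapping, truth: Mapping, ci_key: str = "ci95"
) -> pd.DataFrame:
    """Tabulate estimated vs true quantities.

    ``estimates`` maps labels to either scalars or objects with ``rate`` and
    ``ci95`` attributes; ``truth`` maps the same labels to true values.
    Reports relative error and, where a CI is available, a coverage flag.
    """
    rows = []
    for label, est in estimates.items():
        true = truth.get(label)
        if hasattr(est, "rate"):
            value = est.rate
            lo, hi = getattr(est, ci_key)
            covered = None if true is None else bool(lo <= true <= hi)
        else:
            value = float(est)
            covered = None
        rel_err = None if not true else (value - true) / true
        rows.append({"label": label, "estimate": value, "truth": true,
                     "rel_error": rel_err, "ci_covers_truth": covered})
    return pd.DataFrame(rows, columns=["label", "estimate", "truth", "rel_error", "ci_covers_truth"])
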