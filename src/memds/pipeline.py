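"""End-to-end runs: configuration, the processing pipeline, and reports.

A run consumes a YAML configuration naming the samples (donor, group,
treatment, identifier sequences, FASTQ paths, mix parameters), processes
all reads through structure parsing -> family consensus -> artifact policy
-> molecule counting, then computes per-donor enrichment factors, cells
analyzed and mutation rates.  Every output directory carries a manifest
with the configuration hash and seed; re-running a configuration is
idempotent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .consensus import (
    apply_artifact_policy,
    call_consensus,
    consensus_table,
    count_molecules,
    group_families,
)
from .quantify import (
    EnrichmentExperiment,
    UndefinedEnrichment,
    cells_analyzed,
    enrichment_factor,
    mutation_rate,
    rate_table,
)
from .readproc import process_reads, read_fastq
from .refmodel import ArtifactClassPolicy, ROIModel, hbb_roi, hbd_roi

__all__ = ["RunConfig", "ConfigError", "DataError", "run_pipeline", "report"]


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Unusable input data (exit code 3 at the CLI)."""


@dataclass
class SampleSheetRow:
    donor: str
    treatment: str  # "treated" | "untreated"
    id1: str
    id2: str
    fastq: list[str]
    group: str = ""
    dna_fraction: float = 0.05
    spike_factor: float = 6.0


@dataclass
class RunConfig:
    samples: list[SampleSheetRow]
    rois: dict[str, ROIModel] = field(default_factory=lambda: {"HBB": hbb_roi(), "HBD": hbd_roi()})
    min_phred: int = 28
    trim_window: int = 3
    trim_threshold: int = 30
    min_reads: int = 3
    min_distinct_secondary: int = 2
    min_support_fraction: float = 0.8
    artifact_policy: ArtifactClassPolicy = field(default_factory=ArtifactClassPolicy)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[tuple, tuple] = {}
        for s in self.samples:
            if s.treatment not in ("treated", "untreated"):
                raise ConfigError(f"unknown treatment {s.treatment!r} for donor {s.donor}")
            key = (s.donor, s.treatment)
            if key in seen:
                raise ConfigError(f"duplicate sample for {key}")
            seen[key] = (s.id1, s.id2)
        id1s = [s.id1 for s in self.samples]
        id2s = [s.id2 for s in self.samples]
        if len(set(id1s)) != len(id1s):
            raise ConfigError("ID-1 sequences must be unique per (donor, treatment)")
        if len(set(id2s)) != len(id2s):
            raise ConfigError("ID-2 sequences must be unique per (donor, treatment)")
        for s in self.samples:
            for f in s.fastq:
                if not Path(f).exists():
                    raise ConfigError(f"FASTQ not found: {f}")

    @property
    def id1_map(self) -> dict:
        return {s.id1: (s.donor, s.treatment) for s in self.samples}

    @property
    def id2_map(self) -> dict:
        return {s.id2: (s.donor, s.treatment) for s in self.samples}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        try:
            samples = [
                SampleSheetRow(
                    donor=s["donor"],
                    treatment=s["treatment"],
                    id1=s["id1"],
                    id2=s["id2"],
                    fastq=[str(base / f) for f in s["fastq"]],
                    group=s.get("group", ""),
                    dna_fraction=float(s.get("dna_fraction", 0.05)),
                    spike_factor=float(s.get("spike_factor", 6.0)),
                )
                for s in raw["samples"]
            ]
        except KeyError as exc:
            raise ConfigError(f"sample sheet missing field {exc}") from exc
        rois_spec = raw.get("rois", "builtin")
        if rois_spec == "builtin":
            rois = {"HBB": hbb_roi(), "HBD": hbd_roi()}
        else:
            rois = {}
            for gene, spec in rois_spec.items():
                rois[gene] = ROIModel.from_fasta(
                    base / spec["fasta"],
                    gene,
                    site_span=tuple(spec.get("site_span", (16, 22))),
                    recognition=spec.get("recognition", "CCTNAGG"),
                    discriminator=(
                        tuple(spec.get("discriminator_span", (33, 38))),
                        spec["discriminator"],
                    ),
                )
        th = raw.get("thresholds", {})
        policy = (
            ArtifactClassPolicy.none()
            if raw.get("artifact_policy") == "none"
            else ArtifactClassPolicy()
        )
        return cls(
            samples=samples,
            rois=rois,
            min_phred=int(th.get("min_phred", 28)),
            trim_window=int(th.get("trim_window", 3)),
            trim_threshold=int(th.get("trim_threshold", 30)),
            min_reads=int(th.get("min_reads", 3)),
            min_distinct_secondary=int(th.get("min_distinct_secondary", 2)),
            min_support_fraction=float(th.get("min_support_fraction", 0.8)),
            artifact_policy=policy,
            seed=int(raw.get("seed", 0)),
        )

    def config_hash(self) -> str:
        payload = {
            "samples": [
                (s.donor, s.group, s.treatment, s.id1, s.id2, tuple(s.fastq),
                 s.dna_fraction, s.spike_factor)
                for s in self.samples
            ],
            "rois": {g: (r.cds_sequence, r.site_span, r.recognition, r.discriminator)
                     for g, r in sorted(self.rois.items())},
            "thresholds": (self.min_phred, self.trim_window, self.trim_threshold,
                           self.min_reads, self.min_distinct_secondary,
                           self.min_support_fraction),
            "policy": sorted(self.artifact_policy.excluded_snv_classes_coding_strand),
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, default=str, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute read processing -> consensus -> quantification and write the
    run directory (TSV tables, JSON reports, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = []
    for s in config.samples:
        for f in s.fastq:
            records.extend(read_fastq(f))
    if not records:
        raise DataError("no reads in any input FASTQ")

    accepted, rejects = process_reads(
        records,
        config.rois,
        config.id1_map,
        config.id2_map,
        min_phred=config.min_phred,
        trim_window=config.trim_window,
        trim_threshold=config.trim_threshold,
    )
    families = group_families(accepted)
    calls = [
        apply_artifact_policy(
            call_consensus(
                f,
                min_reads=config.min_reads,
                min_distinct_secondary=config.min_distinct_secondary,
                min_support_fraction=config.min_support_fraction,
            ),
            config.artifact_policy,
        )
        for f in families
    ]
    counts = count_molecules(calls, config.rois)

    consensus_table(calls).to_csv(outdir / "consensus.tsv", sep="\t", index=False)

    from collections import Counter

    size_hist = Counter(f.depth for f in families)
    reject_hist = Counter(reason for _, reason in rejects)
    status_hist = Counter(c.status for c in calls)
    with open(outdir / "qc.json", "w") as fh:
        json.dump(
            {
                "family_size_histogram": {str(k): v for k, v in sorted(size_hist.items())},
                "reject_reasons": dict(sorted(reject_hist.items())),
                "consensus_statuses": dict(sorted(status_hist.items())),
                "n_reads_accepted": len(accepted),
                "n_reads_rejected": len(rejects),
            },
            fh, indent=2,
        )
    pd.DataFrame(rejects, columns=["read_id", "reason"]).to_csv(
        outdir / "rejected_reads.tsv", sep="\t", index=False
    )

    count_rows = []
    for (donor, treatment, gene), mc in sorted(counts.items()):
        count_rows.append(
            {
                "donor": donor, "treatment": treatment, "gene": gene,
                "W": mc.W, "mutant": mc.mutant_molecules, "S": mc.S,
                "R_total": int(sum(mc.R.values())),
                "R_by_variant": json.dumps(dict(sorted(mc.R.items()))),
                "M_by_mutation": json.dumps(dict(sorted(mc.M.items()))),
                "families": mc.families, "discarded": mc.discarded, "ambiguous": mc.ambiguous,
            }
        )
    pd.DataFrame(count_rows).to_csv(outdir / "counts.tsv", sep="\t", index=False)

    mix = {s.donor: (s.dna_fraction, s.spike_factor)
           for s in config.samples if s.treatment == "untreated"}
    groups = {s.donor: s.group for s in config.samples}
    sample_report = {}
    rate_frames = []
    for donor in sorted({d for d, _, _ in counts}):
        for gene in sorted(config.rois):
            t = counts.get((donor, "treated", gene))
            u = counts.get((donor, "untreated", gene))
            if t is None:
                continue
            entry = {
                "donor": donor, "group": groups.get(donor, ""), "gene": gene,
                "W": t.W, "M": t.mutant_molecules,
                "mutations": dict(sorted(t.M.items())),
            }
            if u is not None and donor in mix:
                f_D, f_S = mix[donor]
                try:
                    E = enrichment_factor(
                        EnrichmentExperiment(
                            t.S, int(sum(t.R.values())), u.S, int(sum(u.R.values())),
                            dna_fraction_untreated=f_D, spike_factor_untreated=f_S,
                        )
                    )
                    N = cells_analyzed(E, t.W, t.mutant_molecules)
                    entry["E"] = E
                    entry["N"] = N
                    ests = [
                        mutation_rate(x, N, label=name)
                        for name, x in sorted(t.M.items())
                    ]
                    rate_frames.append(rate_table(ests, group=groups.get(donor, ""), gene=gene)
                                       .assign(donor=donor))
                except UndefinedEnrichment as exc:
                    entry["E_error"] = str(exc)
            sample_report[f"{donor}/{gene}"] = entry
    rate_frames = [f for f in rate_frames if not f.empty]
    rates = (
        pd.concat(rate_frames, ignore_index=True)
        if rate_frames
        else pd.DataFrame(columns=["group", "gene", "mutation", "x", "N", "rate",
                                   "ci_lo", "ci_hi", "expected", "fold", "donor"])
    )
    rates.to_csv(outdir / "rates.tsv", sep="\t", index=False)

    with open(outdir / "report.json", "w") as fh:
        json.dump(sample_report, fh, indent=2, default=str)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {"version": __version__, "config_hash": config.config_hash(), "seed": config.seed},
            fh, indent=2,
        )
    return outdir


def report(run_dir) -> str:
    """Human-readable per-donor summary of a completed run."""
    run_dir = Path(run_dir)
    with open(run_dir / "report.json") as fh:
        sample_report = json.load(fh)
    lines = []
    header = f"{'donor':<10}{'gene':<6}{'N (cells)':>14}{'E':>12}{'W':>8}{'M':>4}  mutations"
    lines.append(header)
    lines.append("-" * len(header))
    pooled: dict[tuple, dict] = {}
    for key, entry in sorted(sample_report.items()):
        muts = ";".join(f"{k}x{v}" for k, v in entry.get("mutations", {}).items()) or "-"
        n = entry.get("N")
        e = entry.get("E")
        lines.append(
            f"{entry['donor']:<10}{entry['gene']:<6}"
            f"{(f'{n:.4g}' if n else 'n/a'):>14}{(f'{e:.4g}' if e else 'n/a'):>12}"
            f"{entry['W']:>8}{entry['M']:>4}  {muts}"
        )
        g = (entry.get("group") or "all", entry["gene"])
        agg = pooled.setdefault(g, {"N": 0.0, "M": 0, "x": {}})
        if n:
            agg["N"] += n
        agg["M"] += entry["M"]
        for name, x in entry.get("mutations", {}).items():
            agg["x"][name] = agg["x"].get(name, 0) + x
    lines.append("")
    lines.append("pooled:")
    for (group, gene), agg in sorted(pooled.items()):
        if agg["N"] <= 0:
            continue
        for name, x in sorted(agg["x"].items()):
            est = mutation_rate(x, agg["N"], label=name)
            lines.append(
                f"  {group:<8}{gene:<6}{name:<14} x={x:<4} N={agg['N']:.4g} "
                f"rate={est.rate:.3g} CI=({est.ci95[0]:.3g}, {est.ci95[1]:.3g})"
            )
    return "\n".join(lines)
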