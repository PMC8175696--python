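"""Pipeline orchestration: configuration, stage ordering, run manifest.

Stages run in dependency order — simulate (optional) → Ks estimation →
WGD inference → hotspot scan → SI classification — each enabled by the
presence of its inputs in the configuration. Every run writes a manifest
recording the tool version, the configuration snapshot, input checksums
and per-stage record counts, so identical configurations and seeds yield
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .errors import InputError
from . import hotspots as hs
from . import io as wio
from . import ks as ksmod
from . import si as simod
from . import wgd as wgdmod


@dataclasses.dataclass
class PipelineConfig:
    """Flat configuration; every field has a CLI flag and a config key."""

    # hotspot scan
    window: int = hs.DEFAULT_WINDOW
    step: int | None = None
    dp_min: float = 2
    dp_max: float = 20
    qual_min: float = 20
    count_cutoff: float = hs.DEFAULT_COUNT_CUTOFF
    rate_cutoff: float = hs.DEFAULT_RATE_CUTOFF
    # wgd inference
    anchor_range: tuple[float, float] = wgdmod.DEFAULT_ANCHOR_RANGE
    global_range: tuple[float, float] = wgdmod.DEFAULT_GLOBAL_RANGE
    bandwidth: str | float = "silverman"
    # si classification
    pi_min: float = simod.SI_PI_BAND[0]
    pi_max: float = simod.SI_PI_BAND[1]
    flank_bp: int = 1_000_000
    # run plumbing
    seed: int = 0
    outdir: str = "wgtkit_out"
    # stage inputs (a stage runs iff its inputs are set)
    pairs_fasta: str | None = None
    pairs_tsv: str | None = None
    dating_table: str | None = None
    vcf: str | None = None
    lengths: str | None = None
    gff: str | None = None
    term_map: str | None = None
    proteome: str | None = None
    membership: str | None = None
    fbox: str | None = None

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise InputError("window must be positive")
        if self.step is not None and self.step > self.window:
            raise InputError("step must not exceed window")
        if not (self.pi_min < self.pi_max and self.anchor_range[0] < self.anchor_range[1]
                and self.global_range[0] < self.global_range[1]):
            raise InputError("ranges must be ordered")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key = value config file (``#`` comments allowed)."""
        kwargs: dict[str, Any] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise InputError(f"{path}:{lineno}: expected key = value")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise InputError(f"{path}:{lineno}: unknown config key {key!r}")
                kwargs[key] = _coerce(key, value)
        return cls(**kwargs)


def _coerce(key: str, value: str) -> Any:
    if key in ("anchor_range", "global_range"):
        lo, hi = value.split(",")
        return (float(lo), float(hi))
    if key in ("window", "step", "flank_bp", "seed"):
        return int(value)
    if key in ("dp_min", "dp_max", "qual_min", "count_cutoff", "rate_cutoff",
               "pi_min", "pi_max"):
        return float(value)
    if key == "bandwidth":
        try:
            return float(value)
        except ValueError:
            return value
    return value


@dataclasses.dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: dict[str, str]
    stage_counts: dict[str, dict]
    warnings: list[str]
    timings_s: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _checksum(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _read_pairs(config: PipelineConfig) -> tuple[list[tuple[str, str]], list[str]]:
    seqs = wio.read_fasta(config.pairs_fasta)
    pairs, labels = [], []
    if config.pairs_tsv:
        table = pd.read_csv(config.pairs_tsv, sep="\t", header=None, names=["id_a", "id_b"])
        for row in table.itertuples():
            for gid in (row.id_a, row.id_b):
                if gid not in seqs:
                    raise InputError(f"pair member {gid!r} missing from {config.pairs_fasta}")
            pairs.append((seqs[row.id_a], seqs[row.id_b]))
            labels.append(f"{row.id_a}-{row.id_b}")
    else:
        ids = list(seqs)
        if len(ids) % 2:
            raise InputError("concatenated pair FASTA must hold an even number of records")
        for a, b in zip(ids[::2], ids[1::2]):
            pairs.append((seqs[a], seqs[b]))
            labels.append(f"{a}-{b}")
    return pairs, labels


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage whose inputs are configured; see module docs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checks: dict[str, str] = {}
    for field in ("pairs_fasta", "pairs_tsv", "dating_table", "vcf", "lengths",
                  "gff", "term_map", "proteome", "membership", "fbox"):
        path = getattr(config, field)
        if path is not None:
            if not Path(path).exists():
                raise InputError(f"configured input {field} = {path!r} does not exist")
            checks[field] = _checksum(path)

    counts: dict[str, dict] = {}
    warnings_log: list[str] = []
    timings: dict[str, float] = {}
    dist = None

    if config.pairs_fasta:
        t0 = time.perf_counter()
        pairs, labels = _read_pairs(config)
        frame = ksmod.distribution_to_frame(pairs, labels)
        wio.write_tsv(frame, outdir / "ks_pairs.tsv")
        dist = ksmod.KsDistribution(
            frame.loc[~frame["saturated"] & frame["ks"].notna(), "ks"].to_numpy(),
            frame.loc[~frame["saturated"] & frame["ks"].notna(), "pair_id"].tolist(),
            "paranome",
            int(frame["saturated"].sum()),
        )
        counts["ks"] = {"n_pairs": len(pairs), "n_saturated": dist.saturated_count}
        timings["ks"] = time.perf_counter() - t0

    if dist is not None or config.dating_table:
        t0 = time.perf_counter()
        wgd_summary: dict[str, Any] = {}
        wgd_ks = None
        if dist is not None and len(dist):
            peaks = wgdmod.detect_peaks(dist, search_range=config.anchor_range,
                                        bandwidth=config.bandwidth)
            wgd_summary["modes"] = [m.ks_mode for m in peaks.modes]
            if peaks.primary:
                wgd_ks = peaks.primary.ks_mode
        if config.dating_table and wgd_ks is not None:
            events = wgdmod.events_from_frame(wio.read_dating_table(config.dating_table))
            placement = wgdmod.place_wgd(wgd_ks, events)
            dating = wgdmod.date_wgd(wgd_ks, events)
            wgd_summary.update(
                wgd_ks=wgd_ks,
                older_than=[e.species_pair[1] for e in placement.older_than],
                younger_than=(placement.younger_than.species_pair[1]
                              if placement.younger_than else None),
                age_min=dating.age_min, age_max=dating.age_max, age_mean=dating.age_mean,
            )
        (outdir / "wgd_summary.json").write_text(json.dumps(wgd_summary, indent=2))
        counts["wgd"] = {"n_modes": len(wgd_summary.get("modes", []))}
        timings["wgd"] = time.perf_counter() - t0

    if config.vcf:
        t0 = time.perf_counter()
        policy = hs.FilterPolicy(config.dp_min, config.dp_max, config.qual_min)
        sites, lengths = hs.filter_variants(config.vcf, policy, config.lengths)
        windows = hs.window_counts(sites, lengths, config.window, config.step)
        hotspot_set = hs.call_hotspots(windows, config.count_cutoff, config.rate_cutoff)
        wio.write_bed(
            ((w.chrom, w.start, w.end) for w in hotspot_set.hotspots),
            outdir / "hotspots.bed",
        )
        wio.write_tsv(hotspot_set.per_chromosome, outdir / "hotspots_summary.tsv")
        counts["hotspots"] = {
            "n_het_sites": len(sites),
            "n_windows": len(windows),
            "n_hotspots": hotspot_set.n_hotspots,
            "fraction_het_in_hotspots": hotspot_set.fraction_het_in_hotspots,
        }
        if config.gff:
            genes = wio.read_gff_genes(config.gff)
            gene_set = hs.genes_in_hotspots(hotspot_set, genes)
            (outdir / "hotspot_genes.txt").write_text("\n".join(sorted(gene_set)) + "\n")
            counts["hotspots"]["n_genes"] = len(gene_set)
            if config.term_map:
                term_df = pd.read_csv(config.term_map, sep="\t", header=None,
                                      names=["gene", "term"])
                table = hs.enrichment(gene_set, {g.id for g in genes}, term_df)
                wio.write_tsv(table, outdir / "enrichment.tsv")
                counts["hotspots"]["n_terms"] = len(table)
        timings["hotspots"] = time.perf_counter() - t0

    if config.proteome and config.membership:
        t0 = time.perf_counter()
        proteome = wio.read_fasta(config.proteome)
        members = wio.read_id_list(config.membership)
        verdicts = simod.classify(proteome, members, (config.pi_min, config.pi_max))
        frame = pd.DataFrame(
            {
                "id": [v.id for v in verdicts],
                "has_pattern4": [v.has_pattern4 for v in verdicts],
                "positions": [",".join(map(str, v.pattern4_positions)) for v in verdicts],
                "pI": [round(v.pI, 3) for v in verdicts],
                "candidate": [v.is_srnase_candidate for v in verdicts],
            }
        )
        wio.write_tsv(frame, outdir / "si_classification.tsv")
        counts["si"] = {
            "n_members": len(verdicts),
            "n_candidates": int(frame["candidate"].sum()),
        }
        if config.gff and config.fbox:
            genes = wio.read_gff_genes(config.gff)
            fbox = wio.read_id_list(config.fbox)
            cands = frame.loc[frame["candidate"], "id"].tolist()
            cands = [c for c in cands if any(g.id == c for g in genes)]
            loci = simod.find_slocus(cands, genes, fbox, config.flank_bp)
            counts["si"]["n_slocus"] = len(loci)
            (outdir / "slocus.json").write_text(
                json.dumps([dataclasses.asdict(l) for l in loci], indent=2)
            )
        timings["si"] = time.perf_counter() - t0

    manifest = RunManifest(
        version=__version__,
        config=dataclasses.asdict(config),
        input_checksums=checks,
        stage_counts=counts,
        warnings=warnings_log,
        timings_s=timings,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
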