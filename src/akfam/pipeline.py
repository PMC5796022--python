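"""End-to-end orchestration: screen -> cluster -> project -> dnds ->
window -> domains, driven by a single declarative YAML config.

Each stage is skippable; every output file is recorded in a manifest with
its SHA-256 checksum so a rerun with the same config and seed can be
verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clustering import cluster_identity_matrix
from .codon_align import CodonAlignment, project_gaps
from .domains import region_summaries, summaries_to_frame
from .io_formats import (
    read_domain_map,
    read_fasta,
    read_hit_table,
    read_identity_matrix,
    read_species_map,
    write_fasta,
    write_hit_table,
    write_tsv,
)
from .ng86 import all_pairs_dnds
from .screen import FilterThresholds, apply_blocklist, attach_species, dedupe_by_species, filter_hits
from .windows import per_species_profiles, sliding_profile

log = logging.getLogger("akfam")

STAGES = ("screen", "cluster", "project", "dnds", "window", "domains")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # inputs
    hits: Path | None = None
    species_map: Path | None = None
    blocklist: tuple[str, ...] = ()
    identity: Path | None = None
    protein_aln: Path | None = None
    cds: Path | None = None
    codon_aln: Path | None = None  # alternative to protein_aln + cds
    domain_map: Path | None = None
    reference_id: str | None = None
    groups: Path | None = None  # two-column TSV id -> group, for per-species windows
    # parameters
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    window_sizes: tuple[int, ...] = (10, 30)
    window_step: int = 1
    genetic_code: int = 1
    zero_ds_policy: str = "drop"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if any(w < 2 for w in self.window_sizes):
            raise ConfigError("window sizes must be >= 2 codons")
        requirements = {
            "screen": ["hits"],
            "cluster": ["identity"],
            "dnds": [],
            "window": [],
            "domains": ["domain_map"],
        }
        if "project" in self.stages:
            if not (self.protein_aln and self.cds):
                raise ConfigError("project stage needs protein_aln and cds")
        elif any(s in self.stages for s in ("dnds", "window", "domains")):
            if not self.codon_aln:
                raise ConfigError(
                    "dnds/window/domains need codon_aln when project is skipped"
                )
        for stage, needs in requirements.items():
            if stage in self.stages:
                for attr in needs:
                    if getattr(self, attr) is None:
                        raise ConfigError(f"stage {stage!r} needs {attr!r}")
        for attr in ("hits", "species_map", "identity", "protein_aln", "cds",
                     "codon_aln", "domain_map", "groups"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{attr} file {p} does not exist")
        if "domains" in self.stages and not self.reference_id:
            raise ConfigError("domains stage needs reference_id")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    for key in ("outdir", "hits", "species_map", "identity", "protein_aln",
                "cds", "codon_aln", "domain_map", "groups"):
        if kwargs.get(key) is not None:
            kwargs[key] = Path(kwargs[key])
    if "thresholds" in kwargs and isinstance(kwargs["thresholds"], dict):
        kwargs["thresholds"] = FilterThresholds(**kwargs["thresholds"])
    for key in ("stages", "window_sizes", "blocklist"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "outdir" not in kwargs:
        raise ConfigError("config needs an 'outdir'")
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Run the enabled stages in order; returns {output path: sha256}.

    The manifest is also written to <outdir>/manifest.json together with
    the package version and seed."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log.info("akfam %s, seed %d, stages: %s", __version__, cfg.seed, ", ".join(cfg.stages))

    if "screen" in cfg.stages:
        hits = read_hit_table(cfg.hits)
        log.info("screen: %d hits read", len(hits))
        species = read_species_map(cfg.species_map) if cfg.species_map else None
        hits = attach_species(hits, species)
        if cfg.blocklist:
            hits = apply_blocklist(hits, cfg.blocklist)
        kept = filter_hits(hits, cfg.thresholds)
        if all(h.subject_species for h in kept):
            kept = dedupe_by_species(kept)
        log.info("screen: %d hits kept", len(kept))
        p = out / "screened_hits.tsv"
        write_hit_table(kept, p)
        written.append(p)

    if "cluster" in cfg.stages:
        m = read_identity_matrix(cfg.identity)
        res = cluster_identity_matrix(m)
        log.info("cluster: %d sequences", m.n)
        for name, payload in (
            ("row_dendrogram.nwk", res.row_tree.to_newick()),
            ("col_dendrogram.nwk", res.col_tree.to_newick()),
        ):
            p = out / name
            p.write_text(payload + "\n")
            written.append(p)
        p = out / "identity_reordered.tsv"
        res.reordered.to_csv(p, sep="\t")
        written.append(p)
        p = out / "identity_zscored.tsv"
        res.zscored.to_csv(p, sep="\t")
        written.append(p)

    aln: CodonAlignment | None = None
    if "project" in cfg.stages:
        protein = read_fasta(cfg.protein_aln, "protein")
        cds = {r.id: r.residues for r in read_fasta(cfg.cds, "nucleotide")}
        aln = project_gaps(protein, cds, cfg.genetic_code)
        log.info("project: %d rows x %d codon columns", aln.n_rows, aln.codon_columns)
        p = out / "codon_alignment.fasta"
        write_fasta(aln.to_records(), p)
        written.append(p)
    elif cfg.codon_aln:
        aln = CodonAlignment.from_records(read_fasta(cfg.codon_aln, "nucleotide"))

    if "dnds" in cfg.stages:
        assert aln is not None
        table = all_pairs_dnds(aln, table_id=cfg.genetic_code,
                               zero_ds_policy=cfg.zero_ds_policy)
        log.info("dnds: %d pairs", len(table))
        p = out / "pairwise_rates.tsv"
        write_tsv(table, p)
        written.append(p)

    if "window" in cfg.stages:
        assert aln is not None
        groups = read_species_map(cfg.groups) if cfg.groups else None
        for w in cfg.window_sizes:
            profile = sliding_profile(
                aln, w, cfg.window_step, table_id=cfg.genetic_code,
                zero_ds_policy=cfg.zero_ds_policy,
            )
            p = out / f"window_profile_w{w}.tsv"
            write_tsv(profile.table, p)
            written.append(p)
            if groups:
                for grp, prof in per_species_profiles(
                    aln, groups, w, cfg.window_step, table_id=cfg.genetic_code,
                    zero_ds_policy=cfg.zero_ds_policy,
                ).items():
                    p = out / f"window_profile_w{w}_{grp}.tsv"
                    write_tsv(prof.table, p)
                    written.append(p)
        log.info("window: sizes %s", list(cfg.window_sizes))

    if "domains" in cfg.stages:
        assert aln is not None
        dm = read_domain_map(cfg.domain_map, reference_id=cfg.reference_id)
        summaries = region_summaries(
            aln, dm.reference_id, dm, table_id=cfg.genetic_code,
            zero_ds_policy=cfg.zero_ds_policy,
        )
        log.info("domains: %d regions", len(summaries))
        p = out / "region_summaries.tsv"
        write_tsv(summaries_to_frame(summaries), p)
        written.append(p)

    manifest = {str(p.relative_to(out)): _sha256(p) for p in written}
    meta = {"version": __version__, "seed": cfg.seed, "outputs": manifest}
    (out / "manifest.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return manifest
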