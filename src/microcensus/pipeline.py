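"""End-to-end orchestration: simulate -> profile -> enrich -> census -> qc ->
metabolic -> primers -> synteny, with a machine-readable run manifest.

A run is configured from a single TOML or YAML file (auto-detected by
extension); command-line flags override config values. Each stage writes
its TSV outputs into the run directory and the manifest records the seed,
package version, configuration and a sha256 checksum of every input and
output file, which is sufficient to re-run byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import census as mcensus
from . import coverage, enrichment, io as mio, metabolic, qc as mqc, simulate, synteny
from .primers import load_primer_pairs, screen_sequences

STAGES = (
    "simulate", "profile", "enrich", "census", "qc", "metabolic", "primers",
    "synteny",
)


class ConfigError(ValueError):
    """The run configuration is invalid or references missing inputs."""


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix in {".toml", ".tml"}:
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise ConfigError(f"stage {stage!r}: missing input file {path}")
    return path


def run_pipeline(
    config: dict,
    outdir: str | Path,
    seed: int | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Run the enabled stages in dependency order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    if seed is None:
        seed = int(config.get("seed", 0))

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config": config,
        "outputs": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["outputs"].setdefault(stage, {}).update(
            {p.name: _sha256(p) for p in paths}
        )

    data_dir = outdir

    if "simulate" in stages:
        sim_cfg = dict(config.get("simulate", {}))
        sim_cfg.pop("enabled", None)
        sim_cfg["seed"] = seed
        if "genome_length_bp" in sim_cfg:
            sim_cfg["genome_length_bp"] = tuple(sim_cfg["genome_length_bp"])
        if "enrichment_range" in sim_cfg:
            sim_cfg["enrichment_range"] = tuple(sim_cfg["enrichment_range"])
        try:
            spec = simulate.CommunitySpec(**sim_cfg)
        except (TypeError, simulate.InvalidSpecError) as exc:
            raise ConfigError(f"stage 'simulate': {exc}") from exc
        community = simulate.build_community(spec)
        simulate.write_dataset(community, data_dir)
        record(
            "simulate",
            *(data_dir / n for n in (
                "lengths.tsv", "bins.tsv", "depth_bulk.tsv",
                "depth_concentrate.tsv", "truth.json", "16s.fasta",
                "operons.gff3", "gene_hits.tsv",
            )),
        )
    else:
        data_dir = Path(config.get("inputs", {}).get("dir", outdir))

    lengths_path = data_dir / config.get("inputs", {}).get("lengths", "lengths.tsv")
    bins_path = data_dir / config.get("inputs", {}).get("bins", "bins.tsv")

    bin_tables: dict[str, pd.DataFrame] = {}
    if "profile" in stages:
        prof_cfg = config.get("profile", {})
        min_depth = int(prof_cfg.get("breadth_min_depth", 1))
        lengths = mio.read_lengths(_require(lengths_path, "profile"))
        membership = mio.read_bins(_require(bins_path, "profile"))
        for sample in simulate.SAMPLES:
            depth_path = _require(data_dir / f"depth_{sample}.tsv", "profile")
            table = mio.read_depth_tsv(depth_path)
            profiles = coverage.profile_sample(table, lengths, sample, min_depth)
            coverage.write_profiles_tsv(outdir / f"profiles_{sample}.tsv", profiles)
            scaffold_ra = coverage.relative_abundance(profiles)
            scaffold_ra.to_csv(outdir / f"abundance_scaffold_{sample}.tsv", sep="\t")
            _, bin_df = coverage.aggregate_bins(profiles, membership, lengths)
            bin_df.to_csv(outdir / f"abundance_bin_{sample}.tsv", sep="\t")
            bin_tables[sample] = bin_df
            record(
                "profile",
                outdir / f"profiles_{sample}.tsv",
                outdir / f"abundance_scaffold_{sample}.tsv",
                outdir / f"abundance_bin_{sample}.tsv",
            )

    if "enrich" in stages:
        enr_cfg = config.get("enrich", {})
        floor = enr_cfg.get("floor")
        if floor is None:
            mapped = enr_cfg.get("mapped_bases_bulk")
            read_len = enr_cfg.get("read_length", 150)
            if mapped is None:
                mapped = float(config.get("simulate", {}).get("seq_bases_bulk", 2e8))
            floor = enrichment.default_detection_floor(float(mapped), float(read_len))
        bulk = pd.read_csv(
            _require(outdir / "abundance_scaffold_bulk.tsv", "enrich"),
            sep="\t", index_col="scaffold_id",
        )["base_fraction"].fillna(0.0)
        conc = pd.read_csv(
            _require(outdir / "abundance_scaffold_concentrate.tsv", "enrich"),
            sep="\t", index_col="scaffold_id",
        )["base_fraction"].fillna(0.0)
        table = enrichment.enrichment_table(bulk, conc, float(floor))
        table.to_csv(outdir / "enrichment_scaffold.tsv", sep="\t")
        membership = mio.read_bins(_require(bins_path, "enrich"))
        summary = enrichment.summarize_enrichment(
            enrichment.results_from_table(table), membership
        )
        summary.to_csv(outdir / "enrichment_bin_summary.tsv", sep="\t")
        record("enrich", outdir / "enrichment_scaffold.tsv",
               outdir / "enrichment_bin_summary.tsv")

    if "census" in stages:
        cen_cfg = config.get("census", {})
        params = mcensus.CensusParameters(
            total_cells_per_gram=float(cen_cfg.get("n_total", 1e9)),
            dna_yield_ng_per_gram=cen_cfg.get("dna_yield_ng"),
            model=cen_cfg.get("model", "cell_fraction"),
        )
        sample = cen_cfg.get("sample", "bulk")  # census of the soil community
        sample_bins = bin_tables.get(sample)
        if sample_bins is None:
            sample_bins = pd.read_csv(
                _require(outdir / f"abundance_bin_{sample}.tsv", "census"),
                sep="\t", index_col="bin_id",
            )
        col = "cell_fraction" if params.model == "cell_fraction" else "base_fraction"
        lengths_by_bin = sample_bins["length_bp"] if "length_bp" in sample_bins else None
        table = mcensus.census_table(
            sample_bins[col].fillna(0.0), params,
            None if lengths_by_bin is None else lengths_by_bin.to_dict(),
        )
        table.to_csv(outdir / "census.tsv", sep="\t")
        record("census", outdir / "census.tsv")

    hits_path = data_dir / config.get("inputs", {}).get("gene_hits", "gene_hits.tsv")
    if "qc" in stages:
        qc_cfg = config.get("qc", {})
        scg = mqc.load_scg_set(qc_cfg.get("scg_set"))
        hits = pd.read_csv(
            _require(hits_path, "qc"), sep="\t", comment="#",
            names=["bin_id", "gene_id"],
        )
        reports = mqc.score_bins(hits, scg)
        table = mqc.qc_table(
            reports,
            float(qc_cfg.get("min_completeness", 70.0)),
            float(qc_cfg.get("max_contamination", 10.0)),
        )
        table.to_csv(outdir / "qc.tsv", sep="\t")
        record("qc", outdir / "qc.tsv")

    if "metabolic" in stages:
        met_cfg = config.get("metabolic", {})
        panel = metabolic.MarkerPanel.from_tsv(met_cfg.get("panel"))
        hits = pd.read_csv(
            _require(hits_path, "metabolic"), sep="\t", comment="#",
            names=["bin_id", "gene_id"],
        )
        bin_hits = {
            str(b): grp["gene_id"].astype(str).tolist()
            for b, grp in hits.groupby("bin_id")
        }
        table = metabolic.build_profile_table(bin_hits, panel)
        metabolic.write_profile_tsv(outdir / "metabolic_profile.tsv", table)
        record("metabolic", outdir / "metabolic_profile.tsv")

    if "primers" in stages:
        pri_cfg = config.get("primers", {})
        fasta = _require(
            data_dir / config.get("inputs", {}).get("sixteen_s", "16s.fasta"),
            "primers",
        )
        pairs = load_primer_pairs(pri_cfg.get("pairs"))
        seqs = mio.read_fasta(fasta)
        table = screen_sequences(seqs, pairs, k=pri_cfg.get("k"))
        table.to_csv(outdir / "primer_screen.tsv", sep="\t", index=False)
        summary = (
            table.groupby("pair")["detectable"]
            .agg(n_sequences="count", n_detectable="sum")
            .assign(n_undetectable=lambda d: d.n_sequences - d.n_detectable)
        )
        summary.to_json(outdir / "primer_summary.json", indent=1)
        record("primers", outdir / "primer_screen.tsv",
               outdir / "primer_summary.json")

    if "synteny" in stages:
        syn_cfg = config.get("synteny", {})
        gff = _require(
            data_dir / config.get("inputs", {}).get("gff", "operons.gff3"), "synteny"
        )
        model = synteny.OperonModel(
            max_intergenic_gap_bp=int(syn_cfg.get("max_intergenic_gap_bp", 500))
        )
        genes = mio.read_gff3(gff)
        clusters = synteny.extract_clusters(genes, model)
        comparisons = [synteny.classify_cluster(c, model) for c in clusters]
        table = synteny.comparisons_table(comparisons)
        table.to_csv(outdir / "synteny.tsv", sep="\t", index=False)
        with open(outdir / "synteny_diagrams.txt", "w") as fh:
            for c in clusters:
                fh.write(synteny.render_diagram(c) + "\n")
        record("synteny", outdir / "synteny.tsv", outdir / "synteny_diagrams.txt")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
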