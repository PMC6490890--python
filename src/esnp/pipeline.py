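"""End-to-end orchestration: GWAS catalog to allele-specific enhancer SNPs.

Stages run in the canonical order — catalog filtering, independent-signal
clustering, LD proxy expansion, enhancer-window scoring, strong-LD
filtering, genomic-context annotation with promoter exclusion, and
allele-specific motif scoring — each stage writing a typed TSV intermediate
under the output directory so a run is restartable and auditable.  The run
report reconciles per-stage counts (filtering stages never increase a
count; proxy expansion is the one count-increasing stage and is reported
separately) and echoes the full configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import esnp
from esnp import annotation, enhancer, gwas, io as eio, ld, motif

logger = logging.getLogger(__name__)

STAGES = ["filter_catalog", "cluster_signals", "expand_proxies", "call_esnps",
          "strong_ld_filter", "promoter_filter", "allelic_binding"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    catalog: str
    panel_matrix: str
    panel_variants: str
    genome: str
    genes: str
    pwms: str
    states: str
    tf_peaks: str
    signal_tracks: dict[str, str]   # mark -> bedGraph path
    peak_tracks: dict[str, str]     # mark -> BED path
    training_windows: str
    outdir: str
    seed: int = 0
    p_max: float = gwas.P_MAX
    platform_min: int = gwas.PLATFORM_MIN
    gap_bp: int = gwas.GAP_BP
    r2_proxy: float = 0.3
    proxy_window_bp: int = ld.PROXY_WINDOW_BP
    r2_strong: float = 0.8
    dprime_strong: float = 0.9
    enhancer_cutoff: float = enhancer.DEFAULT_CUTOFF
    promoter_window: tuple[int, int] = annotation.PROMOTER_WINDOW
    promoter_mode: str = "tss"      # "tss" | "state"
    percentile_threshold: float = motif.PERCENTILE_THRESHOLD
    traits: tuple[str, ...] = gwas.LIPID_TRAITS
    ancestries: tuple[str, ...] = ("European", "European-American")
    use_ld_in_clustering: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        base = Path(path).resolve().parent
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("catalog", "panel_matrix", "panel_variants", "genome",
                    "genes", "pwms", "states", "tf_peaks", "training_windows"):
            if key in doc and not Path(doc[key]).is_absolute():
                doc[key] = str(base / doc[key])
        for key in ("signal_tracks", "peak_tracks"):
            if key in doc:
                doc[key] = {m: str(base / p) if not Path(p).is_absolute() else p
                            for m, p in doc[key].items()}
        if "outdir" in doc and not Path(doc["outdir"]).is_absolute():
            doc["outdir"] = str(base / doc["outdir"])
        if "promoter_window" in doc:
            doc["promoter_window"] = tuple(doc["promoter_window"])
        for key in ("traits", "ancestries"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, outdir: str | Path,
                      seed: int = 0, **overrides) -> "RunConfig":
        """Build a config straight from a synthetic-study manifest."""
        manifest_path = Path(manifest_path)
        doc = json.loads(manifest_path.read_text())
        base = manifest_path.parent
        art = doc["artifacts"]
        marks = sorted(k.removeprefix("signal_") for k in art if k.startswith("signal_"))
        kwargs = dict(
            catalog=str(base / art["catalog"]),
            panel_matrix=str(base / art["panel_matrix"]),
            panel_variants=str(base / art["panel_variants"]),
            genome=str(base / art["genome"]),
            genes=str(base / art["genes"]),
            pwms=str(base / art["pwms"]),
            states=str(base / art["states"]),
            tf_peaks=str(base / art["tf_peaks"]),
            signal_tracks={m: str(base / art[f"signal_{m}"]) for m in marks},
            peak_tracks={m: str(base / art[f"peaks_{m}"]) for m in marks},
            training_windows=str(base / art["training_windows"]),
            outdir=str(outdir),
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def validate(self) -> None:
        for key in ("catalog", "panel_matrix", "panel_variants", "genome",
                    "genes", "pwms", "states", "tf_peaks", "training_windows"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigError(f"{key} path does not exist: {p}")
        for group in (self.signal_tracks, self.peak_tracks):
            for mark, p in group.items():
                if not Path(p).exists():
                    raise ConfigError(f"track {mark} path does not exist: {p}")
        if not (0 < self.enhancer_cutoff < 1):
            raise ConfigError(f"enhancer_cutoff must be in (0,1): {self.enhancer_cutoff}")
        for name, val in (("r2_proxy", self.r2_proxy), ("r2_strong", self.r2_strong),
                          ("dprime_strong", self.dprime_strong)):
            if not (0 <= val <= 1):
                raise ConfigError(f"{name} must be in [0,1]: {val}")
        if self.promoter_mode not in {"tss", "state"}:
            raise ConfigError(f"promoter_mode must be 'tss' or 'state': {self.promoter_mode}")


@dataclass
class RunReport:
    """Per-stage bookkeeping for one pipeline run."""

    counts: dict[str, int] = field(default_factory=dict)
    skipped_seeds: list[str] = field(default_factory=list)
    version: str = esnp.__version__
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "counts": self.counts,
            "skipped_seeds": self.skipped_seeds,
            "version": self.version,
            "config": self.config,
        }, indent=1, sort_keys=True))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage; on failure, move partial outputs to failed/."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(config).items()})
    stage = "setup"
    try:
        # ---- stage 1: catalog filter -------------------------------------
        stage = "filter_catalog"
        records = gwas.read_catalog(config.catalog)
        report.counts["catalog_records"] = len(records)
        filtered = gwas.filter_catalog(
            records, traits=config.traits, ancestries=config.ancestries,
            p_max=config.p_max, platform_min=config.platform_min)
        report.counts["filtered_records"] = len(filtered)
        pd.DataFrame([dataclasses.asdict(r) for r in filtered]).to_csv(
            outdir / "01_filtered_catalog.tsv", sep="\t", index=False)

        # ---- stage 2: independent signals --------------------------------
        stage = "cluster_signals"
        panel = eio.read_panel(config.panel_matrix, config.panel_variants)
        ld_source = None
        if config.use_ld_in_clustering:
            def ld_source(s1: str, s2: str) -> float | None:
                if s1 not in panel or s2 not in panel:
                    return None
                try:
                    return ld.ld_from_haplotypes(panel, s1, s2).r2
                except ld.MonomorphicLocusError:
                    return None
        clusters = gwas.cluster_signals(filtered, ld_source=ld_source,
                                        gap_bp=config.gap_bp, r2_strong=config.r2_strong)
        report.counts["independent_signals"] = len(clusters)
        gwas.clusters_to_frame(clusters).to_csv(
            outdir / "02_signals.tsv", sep="\t", index=False)

        # ---- stage 3: LD proxy expansion ---------------------------------
        stage = "expand_proxies"
        seeds = sorted({r.snp_id for r in filtered})
        expansion = ld.expand_proxies(panel, seeds, r2_min=config.r2_proxy,
                                      window_bp=config.proxy_window_bp)
        report.skipped_seeds = expansion.skipped_seeds
        proxies = expansion.table
        report.counts["proxy_pairs"] = len(proxies)
        report.counts["unique_proxy_snps"] = proxies["proxy_snp"].nunique() if len(proxies) else 0
        proxies.to_csv(outdir / "03_proxies.tsv", sep="\t", index=False,
                       float_format="%.6g")

        # ---- stage 4: enhancer model -------------------------------------
        stage = "call_esnps"
        tracks = enhancer.TrackSet(
            signals={m: eio.read_bedgraph(p) for m, p in sorted(config.signal_tracks.items())},
            peaks={m: eio.read_bed(p) for m, p in sorted(config.peak_tracks.items())},
            states=eio.read_bed(config.states),
            tf_peaks=eio.read_bed(config.tf_peaks),
            marks=tuple(sorted(config.signal_tracks)),
        )
        training = pd.read_csv(config.training_windows, sep="\t")
        train_feats = [
            enhancer.extract_features(str(r.window_id), str(r.chrom), int(r.position), tracks)
            for r in training.itertuples()]
        model = enhancer.train_classifier(
            train_feats, training["label"].astype(bool).tolist(),
            seed=config.seed, cutoff=config.enhancer_cutoff)
        model.to_json(outdir / "enhancer_model.json")

        variants = eio.read_variants(config.panel_variants).set_index("snp_id")
        candidates = sorted(set(proxies["proxy_snp"])) if len(proxies) else []
        windows = [
            enhancer.extract_features(
                snp, str(variants.loc[snp, "chrom"]), int(variants.loc[snp, "position"]), tracks)
            for snp in candidates]
        calls = enhancer.call_esnps(windows, model, cutoff=config.enhancer_cutoff)
        esnp_tab = pd.DataFrame([
            {"snp_id": c.snp_id, "score": c.score, "cutoff": c.cutoff, "is_esnp": c.is_esnp}
            for c in calls])
        esnp_tab.to_csv(outdir / "04_esnp_calls.tsv", sep="\t", index=False,
                        float_format="%.6g")
        esnps = sorted(esnp_tab.loc[esnp_tab["is_esnp"], "snp_id"]) if len(esnp_tab) else []
        report.counts["esnps"] = len(esnps)

        # ---- stage 5: strong LD with the GWAS SNPs -----------------------
        stage = "strong_ld_filter"
        esnp_pairs = proxies[proxies["proxy_snp"].isin(esnps)] if len(proxies) else proxies
        strong = ld.strong_ld_filter(esnp_pairs, r2_min=config.r2_strong,
                                     dprime_min=config.dprime_strong)
        strong.to_csv(outdir / "05_strong_ld.tsv", sep="\t", index=False,
                      float_format="%.6g")
        strong_esnps = sorted(strong["proxy_snp"].unique()) if len(strong) else []
        report.counts["strong_ld_esnps"] = len(strong_esnps)

        # ---- stage 6: annotation + promoter exclusion --------------------
        stage = "promoter_filter"
        genes = annotation.read_gene_models(config.genes)
        loc_rows = []
        for snp in strong_esnps:
            call = annotation.classify_location(
                snp, str(variants.loc[snp, "chrom"]), int(variants.loc[snp, "position"]), genes)
            loc_rows.append({
                "snp_id": snp, "chrom": str(variants.loc[snp, "chrom"]),
                "position": int(variants.loc[snp, "position"]),
                "category": call.category, "genes": ",".join(call.genes),
                "tss_distance": call.tss_distance})
        loc_tab = pd.DataFrame(loc_rows, columns=[
            "snp_id", "chrom", "position", "category", "genes", "tss_distance"])
        if config.promoter_mode == "state":
            annotated = annotation.promoter_filter_by_state(loc_tab, tracks.states)
        else:
            annotated = annotation.promoter_filter(loc_tab, genes,
                                                   promoter_window=config.promoter_window)
        annotated.to_csv(outdir / "06_annotation.tsv", sep="\t", index=False,
                         float_format="%.6g")
        retained = sorted(annotated.loc[annotated["retained"], "snp_id"]) if len(annotated) else []
        report.counts["retained_after_promoter"] = len(retained)

        # ---- stage 7: allele-specific TF binding -------------------------
        stage = "allelic_binding"
        genome = eio.read_fasta(config.genome)
        pwms = motif.load_jaspar(config.pwms)
        allelic_rows = []
        n_allele_specific = 0
        for snp in retained:
            row = variants.loc[snp]
            calls_ = motif.score_snp_against_pwms(
                genome, str(row["chrom"]), int(row["position"]),
                str(row["ref"]), str(row["alt"]), pwms, snp,
                seed=config.seed, threshold=config.percentile_threshold)
            for c in calls_:
                if c.verdict == "allele_specific":
                    n_allele_specific += 1
                allelic_rows.append({
                    "snp_id": c.snp_id, "tf_name": c.tf_name, "matrix_id": c.matrix_id,
                    "allele1": c.allele1.allele, "allele1_score": c.allele1.score,
                    "allele1_pct": c.allele1.percentile,
                    "allele2": c.allele2.allele, "allele2_score": c.allele2.score,
                    "allele2_pct": c.allele2.percentile,
                    "offset": c.allele1.offset, "strand": c.allele1.strand,
                    "verdict": c.verdict, "preferred_allele": c.preferred_allele or ""})
        allelic = pd.DataFrame(allelic_rows, columns=[
            "snp_id", "tf_name", "matrix_id", "allele1", "allele1_score", "allele1_pct",
            "allele2", "allele2_score", "allele2_pct", "offset", "strand",
            "verdict", "preferred_allele"])
        allelic.to_csv(outdir / "07_allelic.tsv", sep="\t", index=False,
                       float_format="%.6g")
        report.counts["allele_specific_calls"] = n_allele_specific

        # ---- final report table ------------------------------------------
        stage = "final_table"
        final = _final_table(strong, loc_tab if len(loc_tab) else None,
                             annotated, allelic, filtered)
        final.to_csv(outdir / "final_table.tsv", sep="\t", index=False,
                     float_format="%.6g")
        report.counts["final_esnps"] = final["esnp"].nunique() if len(final) else 0
        report.to_json(outdir / "report.json")
        return report
    except Exception as exc:  # preserve partial outputs for debugging
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for item in sorted(outdir.iterdir()):
            if item.name != "failed" and item.is_file():
                shutil.move(str(item), str(failed / item.name))
        raise StageError(stage, exc) from exc


def _final_table(strong: pd.DataFrame, loc_tab: pd.DataFrame | None,
                 annotated: pd.DataFrame, allelic: pd.DataFrame,
                 filtered: list) -> pd.DataFrame:
    """Assemble the published-style summary: one row per retained
    (eSNP, GWAS SNP) pair with trait, p-value, gene and TF-verdict columns."""
    cols = ["chrom", "esnp", "gwas_snp", "r2", "d_prime", "traits", "p_value",
            "category", "nearest_genes", "tf_verdicts"]
    if strong is None or not len(strong):
        return pd.DataFrame(columns=cols)
    retained_ids = set(annotated.loc[annotated["retained"], "snp_id"]) if len(annotated) else set()
    by_snp = {}
    for rec in filtered:
        by_snp.setdefault(rec.snp_id, []).append(rec)
    rows = []
    for _, pair in strong.iterrows():
        if pair["proxy_snp"] not in retained_ids:
            continue
        loc = None
        if loc_tab is not None:
            hit = loc_tab[loc_tab["snp_id"] == pair["proxy_snp"]]
            loc = hit.iloc[0] if len(hit) else None
        verdicts = ""
        if len(allelic):
            sub = allelic[(allelic["snp_id"] == pair["proxy_snp"])
                          & (allelic["verdict"] != "none")]
            verdicts = ";".join(
                f"{r.tf_name}:{r.verdict}"
                + (f"({r.preferred_allele})" if r.preferred_allele else "")
                for r in sub.itertuples())
        seed_recs = by_snp.get(pair["seed_snp"], [])
        rows.append({
            "chrom": pair["chrom"],
            "esnp": pair["proxy_snp"],
            "gwas_snp": pair["seed_snp"],
            "r2": pair["r2"],
            "d_prime": pair["d_prime"],
            "traits": ",".join(sorted({r.trait for r in seed_recs})),
            "p_value": min((r.p_value for r in seed_recs), default=float("nan")),
            "category": loc["category"] if loc is not None else "",
            "nearest_genes": loc["genes"] if loc is not None else "",
            "tf_verdicts": verdicts,
        })
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["chrom", "esnp", "gwas_snp"]).reset_index(drop=True)
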