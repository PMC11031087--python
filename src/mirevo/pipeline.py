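"""End-to-end orchestration over synthetic or user-supplied data.

Stages run in a fixed order (simulate -> scan -> de -> det -> cross_species
-> conserve -> popgen -> teorigin -> compete); each stage writes its outputs
plus a manifest (parameters and output hashes) under its own subdirectory,
and a final JSON + text report aggregates the headline statistics.  The
report hash is computed over the canonical JSON of the report, so identical
configurations are checkable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import competition as comp
from . import conservation as cons
from . import cross_species as xsp
from . import de as de_mod
from . import io as mio
from . import simulate as sim
from . import te_origin as te
from .scan import DEFAULT_TIERS, ScanTier, TargetMap, predict_targets

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate",
    "scan",
    "de",
    "det",
    "cross_species",
    "conserve",
    "popgen",
    "teorigin",
    "compete",
)


_STAGE_DEPS = {
    "simulate": (),
    "scan": ("simulate",),
    "de": ("simulate",),
    "det": ("de", "scan"),
    "cross_species": ("det", "scan"),
    "conserve": ("simulate",),
    "popgen": ("simulate",),
    "teorigin": ("simulate",),
    "compete": ("simulate",),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "mirevo_run"
    rng_seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    log_level: str = "INFO"
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    # per-stage parameter blocks
    scan_tiers: tuple[ScanTier, ...] = DEFAULT_TIERS
    fc_min: float = 2.0
    fdr_max: float = 0.05
    min_lines: int = 2
    n_ko_lines: int = 5
    n_perturbed_lines: int = 3
    n_target_genes: int = 60
    sites_per_target: int = 2
    wobble_rate: float = 0.0
    identity_min: float = 0.94
    min_span: int = 50
    n_decoy_tes: int = 3
    assays: tuple[tuple[int, float, tuple[float, float]], ...] = (
        (180, 0.73, (1.0, 1.0)),
        (170, 0.9, (4.0, 1.0)),
        (96, 0.62, (1.0, 1.0)),
    )

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # canonical order regardless of listing order
        self.stages = tuple(s for s in STAGE_ORDER if s in self.stages)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        sim_cfg = sim.SimConfig(**payload.pop("sim", {}))
        tiers = payload.pop("scan_tiers", None)
        kwargs = dict(payload)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "assays" in kwargs:
            kwargs["assays"] = tuple(
                (int(n), float(f), (float(r[0]), float(r[1]))) for n, f, r in kwargs["assays"]
            )
        cfg = cls(sim=sim_cfg, **kwargs)
        if tiers is not None:
            cfg.scan_tiers = tuple(ScanTier(**t) for t in tiers)
        return cfg


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: dict) -> None:
    manifest = {
        "stage": stage,
        "parameters": params,
        "outputs": {
            p.name: _sha256_file(p) for p in sorted(stage_dir.iterdir()) if p.is_file() and p.name != "manifest.json"
        },
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def report_hash(report: dict) -> str:
    return hashlib.sha256(
        json.dumps(report, sort_keys=True, default=str).encode("utf-8")
    ).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages on synthetic data; return the report."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s [%(levelname)s] %(message)s",
    )
    enabled = set(config.stages)
    for stage in config.stages:  # validate before any stage runs
        missing = [d for d in _STAGE_DEPS[stage] if d not in enabled]
        if missing:
            raise ValueError(f"stage {stage!r} requires {missing} in the stage list")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    report: dict = {"seed": config.rng_seed, "stages": list(config.stages)}
    for stage in config.stages:
        logger.info("running stage %s", stage)
        stage_dir = outdir / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        try:
            _STAGES[stage](config, state, report, stage_dir)
        except Exception as exc:  # partial outputs are preserved on disk
            raise PipelineError(stage, exc) from exc
    report["report_hash"] = report_hash(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    (outdir / "report.txt").write_text(_render_report(report))
    return report


def _stage_simulate(cfg: RunConfig, state: dict, report: dict, out: Path) -> None:
    scfg = dataclasses.replace(cfg.sim, rng_seed=cfg.rng_seed)
    families: dict[str, list] = {}
    family_truths: dict[str, sim.FamilyTruth] = {}
    txome = sim.simulate_transcriptome(scfg)
    species = sorted(txome.utrs)
    implanted: dict[str, list] = {}
    all_sites = []
    rng_implant = sim.stage_rng(cfg.rng_seed, "implant")
    ancestor_spec = sim.build_ancestor(scfg)
    for sp in species:
        mirnas, ftruth = sim.simulate_mirna_family(scfg, species=sp, ancestor=ancestor_spec)
        families[sp] = mirnas
        family_truths[sp] = ftruth
        targets = txome.utrs[sp][: cfg.n_target_genes]
        rest = txome.utrs[sp][cfg.n_target_genes :]
        mod, itruth = sim.implant_target_sites(
            targets,
            mirnas,
            sites_per_target=cfg.sites_per_target,
            wobble_rate=cfg.wobble_rate,
            rng=rng_implant,
        )
        implanted[sp] = mod + rest
        all_sites.extend(itruth.sites)
        mio.write_fasta(out / f"mirnas_{sp}.fa", {m.name: m.mature_seq for m in mirnas})
        mio.write_fasta(out / f"utrs_{sp}.fa", {u.transcript: u.seq for u in implanted[sp]})
    mio.write_bed(
        out / "true_sites.bed",
        mio.sites_to_bed(all_sites),
    )
    # KO design: n_ko_lines lines; the first n_perturbed_lines perturb the
    # implanted target genes of species 1 with the configured signed effect
    sp1 = species[0]
    target_genes = sorted({u.gene for u in implanted[sp1][: cfg.n_target_genes]})
    lines = [f"ko{i + 1}" for i in range(cfg.n_ko_lines)]
    rng_fx = sim.stage_rng(cfg.rng_seed, "effects")
    signs = {g: (1.0 if rng_fx.random() < 0.5 else -1.0) for g in target_genes}
    truth_de = {
        line: {g: signs[g] * abs(cfg.sim.target_log2fc) for g in target_genes}
        for line in lines[: cfg.n_perturbed_lines]
    }
    for line in lines[cfg.n_perturbed_lines :]:
        truth_de[line] = {}
    genes = sorted({u.gene for u in implanted[sp1]})
    design = {"WT": cfg.sim.n_replicates, **{ln: cfg.sim.n_replicates for ln in lines}}
    cm = sim.simulate_counts(design, truth_de, scfg, genes)
    mio.write_counts_tsv(out / "counts.tsv", cm)
    track = sim.simulate_conservation_track(
        implanted[sp1],
        [s for s in all_sites if s.transcript.startswith(sp1)],
        base_mean=scfg.base_mean,
        site_elevation_delta=scfg.site_elevation_delta,
        noise_sd=scfg.noise_sd,
        rng=sim.stage_rng(cfg.rng_seed, "conservation"),
    )
    alleles = sim.simulate_population_alleles(
        {
            "piRNA": (300, (2.0, 2.0)),
            "SmiR": (300, (1.0, 6.0)),
            "FmiR": (300, (0.5, 8.0)),
            "all-miRNA": (300, (1.0, 4.0)),
        },
        rng=sim.stage_rng(cfg.rng_seed, "alleles"),
    )
    alleles.to_csv(out / "alleles.tsv", sep="\t", index=False)
    rng_assay = sim.stage_rng(cfg.rng_seed, "assays")
    assays = [
        sim.simulate_competition_assay(n, f, rng=rng_assay, ratio=r, replicate=f"a{i + 1}")
        for i, (n, f, r) in enumerate(cfg.assays)
    ]
    truth = sim.SimTruth(
        ancestor_te=family_truths[sp1].ancestor_te,
        family_tree=family_truths[sp1].parent,
        true_sites=all_sites,
        true_targets={
            sp: {m.name: sorted({s.transcript.split(":", 1)[1].rsplit(".t1", 1)[0] for s in all_sites if s.mirna == m.name}) for m in families[sp]}
            for sp in species
        },
        true_de_genes=truth_de,
        true_fraction=cfg.assays[0][1] if cfg.assays else 0.5,
    )
    (out / "truth.json").write_text(truth.to_json())
    state.update(
        txome=txome,
        families=families,
        family_truths=family_truths,
        implanted=implanted,
        sites=all_sites,
        counts=cm,
        track=track,
        alleles=alleles,
        assays=assays,
        truth=truth,
        lines=lines,
        species=species,
        target_genes=target_genes,
    )
    report["simulate"] = {
        "species": species,
        "n_genes": cfg.sim.n_genes,
        "n_mirnas_per_species": cfg.sim.n_clusters * cfg.sim.mirnas_per_cluster,
        "n_true_sites": len(all_sites),
        "ko_lines": lines,
    }
    _write_manifest(out, "simulate", {"seed": cfg.rng_seed})


def _stage_scan(cfg: RunConfig, state: dict, report: dict, out: Path) -> None:
    maps: dict[str, TargetMap] = {}
    for sp in state["species"]:
        tmap = predict_targets(state["families"][sp], state["implanted"][sp], cfg.scan_tiers)
        maps[sp] = tmap
        tmap.to_frame().to_csv(out / f"targets_{sp}.tsv", sep="\t", index=False)
    state["target_maps"] = maps
    report["scan"] = {
        sp: {"n_sites": len(maps[sp].to_frame()), "n_target_genes": len(maps[sp].target_genes(sp))}
        for sp in state["species"]
    }
    _write_manifest(out, "scan", {"tiers": [t.name for t in cfg.scan_tiers]})


def _stage_de(cfg: RunConfig, state: dict, report: dict, out: Path) -> None:
    records_by_line = {}
    for line in state["lines"]:
        records = de_mod.differential_expression(state["counts"], line)
        records_by_line[line] = records
        de_mod.de_frame(records).to_csv(out / f"de_{line}.tsv", sep="\t", index=False)
    state["de"] = records_by_line
    state["degs"] = {
        line: de_mod.select_degs(recs, fc_min=cfg.fc_min, fdr_max=cfg.fdr_max)
        for line, recs in records_by_line.items()
    }
    report["de"] = {line: len(s) for line, s in state["degs"].items()}
    _write_manifest(out, "de", {"fc_min": cfg.fc_min, "fdr_max": cfg.fdr_max})


def _stage_det(cfg: RunConfig, state: dict, report: dict, out: Path) -> None:
    sp1 = state["species"][0]
    pool = de_mod.select_dets(
        state["degs"],
        state["target_maps"][sp1],
        min_lines=cfg.min_lines,
        species=sp1,
        fc_min=cfg.fc_min,
        fdr_max=cfg.fdr_max,
    )
    state["det_pool"] = pool
    rows = [{"gene": g, "support": n} for g, n in sorted(pool.pooled.items())]
    import pandas as pd

    pd.DataFrame(rows, columns=["gene", "support"]).to_csv(
        out / "pooled_dets.tsv", sep="\t", index=False
    )
    report["det"] = {
        "pooled": len(pool.pooled),
        "all_lines": len(pool.all_lines),
        "per_line": {line: len(s) for line, s in pool.per_line.items()},
    }
    _write_manifest(out, "det", {"min_lines": cfg.min_lines})


def _stage_cross_species(cfg: RunConfig, state: dict, report: dict, out: Path) -> None:
    sp1 = state["species"][0]
    reference = state["det_pool"].pooled_genes or set(state["target_genes"])
    shared = xsp.shared_targets(
        reference, state["target_maps"], state["txome"].orthologs, reference_species=sp1
    )
    universe = {
        g for sp in state["species"] for g in state["target_maps"][sp].target_genes(sp)
    }
    per_mirna = xsp.targets_per_mirna(state["target_maps"], universe)
    per_tx = xsp.sites_per_transcript(state["target_maps"])
    shared.pairwise.to_csv(out / "pairwise_shared.tsv", sep="\t", index=False)
    per_tx.ecdf_frame().to_csv(out / "sites_per_transcript_ecdf.tsv", sep="\t", index=False)
    state["shared"] = shared
    report["cross_species"] = {
        "venn": {"+".join(k): v for k, v in sorted(shared.venn.items())},
        "shared_all": shared.shared_all(),
        "targets_per_mirna_mean": {k: round(v, 3) for k, v in per_mirna.means.items()},
        "targets_per_mirna_p": per_mirna.pvalue,
        "sites_per_transcript_p": per_tx.pvalue,
    }
    _write_manifest(out, "cross_species", {"reference": sp1})


def _stage_conserve(cfg: RunConfig, state: dict, report: dict, out: Path) -> None:
    sp1 = state["species"][0]
    scores_by_gene = {}
    sites_by_gene: dict[str, list] = {}
    by_tx = {}
    for s in state["sites"]:
        by_tx.setdefault(s.transcript, []).append(s)
    for utr in state["implanted"][sp1]:
        if utr.transcript not in by_tx:
            continue
        scores_by_gene[utr.gene] = cons.map_scores_to_utr(state["track"], utr)
        sites_by_gene[utr.gene] = by_tx[utr.transcript]
    contrast = cons.site_vs_nonsite_contrast(scores_by_gene, sites_by_gene)
    contrast.table.to_csv(out / "site_contrast.tsv", sep="\t", index=False)
    state["contrast"] = contrast
    report["conserve"] = {
        "n_genes": contrast.n_genes,
        "mean_difference": round(contrast.mean_difference, 4),
        "paired_p": contrast.pvalue,
    }
    _write_manifest(out, "conserve", {"delta": cfg.sim.site_elevation_delta})


def _stage_popgen(cfg: RunConfig, state: dict, report: dict, out: Path) -> None:
    compare = cons.popgen_class_compare(state["alleles"])
    compare.per_class.to_csv(out / "class_summary.tsv", sep="\t", index=False)
    report["popgen"] = {
        "status": compare.status,
        "daf_kw_p": compare.tests.get("daf", {}).get("kw_pvalue"),
        "mnd_kw_p": compare.tests.get("mnd", {}).get("kw_pvalue"),
    }
    _write_manifest(out, "popgen", {})


def _stage_teorigin(cfg: RunConfig, state: dict, report: dict, out: Path) -> None:
    rng = sim.stage_rng(cfg.rng_seed, "decoy_tes")
    ancestor = state["truth"].ancestor_te
    library = [te.TeRecord(name="ancestorTE", consensus=ancestor)]
    for i in range(cfg.n_decoy_tes):
        library.append(
            te.TeRecord(
                name=f"decoyTE{i + 1}",
                consensus="".join(rng.choice(list("ACGT"), size=len(ancestor))),
            )
        )
    loci = {
        sp: dict(state["family_truths"][sp].loci) for sp in state["species"]
    }
    screen = te.screen_te_sources(
        library, loci, identity_min=cfg.identity_min, min_span=cfg.min_span
    )
    screen.hits.to_csv(out / "te_hits.tsv", sep="\t", index=False)
    hp = te.hairpin_check(ancestor, sequence_id="ancestorTE")
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(hp)]).to_csv(out / "hairpins.tsv", sep="\t", index=False)
    spectrum = te.substitution_spectrum(
        {**{"ancestor": ancestor}, **state["family_truths"][state["species"][0]].loci}
    )
    spectrum.to_frame().to_csv(out / "substitution_spectrum.tsv", sep="\t")
    report["teorigin"] = {
        "top_te": screen.ranking.iloc[0]["te"] if len(screen.ranking) else None,
        "universal": screen.universal,
        "ancestor_is_hairpin": hp.is_hairpin,
        "uc_ag_fraction": round(spectrum.fraction(("U", "C"), ("A", "G")), 4),
    }
    _write_manifest(out, "teorigin", {"identity_min": cfg.identity_min})


def _stage_compete(cfg: RunConfig, state: dict, report: dict, out: Path) -> None:
    rows = []
    for assay in state["assays"]:
        gof = comp.paternity_gof(assay)
        ci = comp.paternity_fraction_ci(assay)
        rows.append(
            {
                "replicate": assay.replicate,
                "count_a": assay.count_a,
                "count_b": assay.count_b,
                "ratio": f"{assay.ratio_a:g}:{assay.ratio_b:g}",
                "chi2": round(gof.chi2, 4),
                "pvalue": gof.pvalue,
                "fraction_a": round(ci.fraction, 4),
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "competition.tsv", sep="\t", index=False)
    report["compete"] = {r["replicate"]: {"chi2": r["chi2"], "p": r["pvalue"]} for r in rows}
    _write_manifest(out, "compete", {})


_STAGES = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "de": _stage_de,
    "det": _stage_det,
    "cross_species": _stage_cross_species,
    "conserve": _stage_conserve,
    "popgen": _stage_popgen,
    "teorigin": _stage_teorigin,
    "compete": _stage_compete,
}


def _render_report(report: dict) -> str:
    lines = ["mirevo pipeline report", "=" * 24]
    for stage in STAGE_ORDER:
        if stage not in report:
            continue
        lines.append(f"\n[{stage}]")
        for k, v in report[stage].items():
            lines.append(f"  {k}: {v}")
    lines.append(f"\nreport hash: {report.get('report_hash', '')}")
    return "\n".join(lines) + "\n"
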