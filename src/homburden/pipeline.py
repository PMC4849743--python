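"""End-to-end pipeline: simulate/load -> ROH -> recurrent -> burden -> inbreeding -> GLM."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import (
    DEFAULT_L_AUTO,
    GenomeLayout,
    GenotypeMatrix,
    apply_maf_filter,
    compute_freqs,
    read_plink_binary,
    read_plink_text,
    write_sample_table,
)
from .sim import make_fixture
from .roh import RohParams, call_rohs, ld_tag_groups, write_segments
from .recurrent import analyze_pools, pool_rohs, write_consensus_bed, write_pools
from .burden import (
    binned_or,
    group_burden_test,
    median_split,
    summarize_burden,
    write_binned,
    write_burden,
)
from .inbreeding import (
    build_profiles,
    measure_correlations,
    per_chromosome_f,
    write_per_chrom,
    write_profiles,
)
from .glm import build_covariates, genotype_pca, logistic_glm, perm_regressor_residuals

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat, fully serializable pipeline configuration.

    Input is either PLINK paths (``ped``/``map`` or ``bed``/``bim``/``fam``)
    or a simulation fixture name; every analysis threshold is an explicit
    field with the study defaults.
    """

    # input
    ped: str = ""
    map: str = ""
    bed: str = ""
    bim: str = ""
    fam: str = ""
    fixture: str = ""
    maf_min: float = 0.05
    # ROH calling
    window_snps: int = 50
    window_het_max: int = 0
    window_miss_max: int = 5
    snp_window_frac: float = 0.05
    min_snps: int = 75
    min_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0
    # recurrent pools
    pool_min_members: int = 6
    pool_min_kb: float = 500.0
    pool_min_snps: int = 75
    # burden
    n_bins: int = 4
    # inbreeding / GLM
    l_auto: int = DEFAULT_L_AUTO
    n_pcs: int = 10
    use_sex: bool = True
    use_missing: bool = True
    n_perm: int = 200
    seed: int = 0
    out_dir: str = "homburden_out"

    def to_flat_text(self) -> str:
        lines = ["# homburden pipeline config"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {ln}: expected 'key = value'")
            key, _, val = (x.strip() for x in line.partition("="))
            if not hasattr(defaults, key):
                raise ValueError(f"{path}: line {ln}: unknown key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(val)
            elif isinstance(current, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_input(cfg: PipelineConfig):
    """Resolve the configured input into a genotype matrix (plus sim truth)."""
    if cfg.fixture:
        gm, truth = make_fixture(cfg.fixture)
        return gm, truth, []
    if cfg.ped and cfg.map:
        for p in (cfg.ped, cfg.map):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        gm = read_plink_text(cfg.ped, cfg.map, maf_min=cfg.maf_min)
        return gm, None, [Path(cfg.ped), Path(cfg.map)]
    if cfg.bed and cfg.bim and cfg.fam:
        for p in (cfg.bed, cfg.bim, cfg.fam):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        gm = read_plink_binary(cfg.bed, cfg.bim, cfg.fam, maf_min=cfg.maf_min)
        return gm, None, [Path(cfg.bed), Path(cfg.bim), Path(cfg.fam)]
    raise ValueError("config must name a fixture, a ped/map pair, or a bed/bim/fam trio")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, writing TSV outputs, a manifest and a text report.

    Returns a dict of in-memory results keyed by stage.  A stage failure
    raises :class:`StageError` naming the stage; outputs written by earlier
    stages are left in place.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.txt").write_text(cfg.to_flat_text())
    results: dict = {}
    stage = "load"
    try:
        gm, truth, input_paths = load_input(cfg)
        compute_freqs(gm)
        results["gm"] = gm
        results["truth"] = truth
        write_sample_table(gm, out / "samples.tsv")

        stage = "roh"
        params = RohParams(
            window_snps=cfg.window_snps,
            window_het_max=cfg.window_het_max,
            window_miss_max=cfg.window_miss_max,
            snp_window_frac=cfg.snp_window_frac,
            min_snps=cfg.min_snps,
            min_kb=cfg.min_kb,
            max_gap_kb=cfg.max_gap_kb,
            min_density_kb_per_snp=cfg.min_density_kb_per_snp,
        )
        segments = call_rohs(gm, params)
        results["segments"] = segments
        write_segments(segments, out / "roh_segments.tsv")

        stage = "recurrent"
        pools = pool_rohs(
            segments,
            min_members=cfg.pool_min_members,
            min_consensus_kb=cfg.pool_min_kb,
            gm=gm,
            min_consensus_snps=cfg.pool_min_snps,
        )
        analyze_pools(pools, gm, n_perm=cfg.n_perm, seed=cfg.seed)
        results["pools"] = pools
        write_pools(pools, out / "recurrent_pools.tsv")
        write_consensus_bed(pools, out / "recurrent_pools.bed")

        stage = "burden"
        summaries = summarize_burden(segments, gm.samples)
        results["burden"] = summaries
        write_burden(summaries, out / "burden.tsv")
        results["burden_tests"] = {
            stat: group_burden_test(
                summaries, gm.samples, stat=stat, n_perm=cfg.n_perm, seed=cfg.seed
            )
            for stat in ("n_rohs", "total_kb", "mean_kb")
        }
        try:
            results["median_split"] = median_split(summaries, by="mean_kb")
        except ValueError:
            results["median_split"] = None
        binned = {}
        for stat in ("n_rohs", "total_kb"):
            try:
                binned[stat] = binned_or(summaries, gm.samples, stat=stat, n_bins=cfg.n_bins)
                write_binned(binned[stat], out / f"binned_or_{stat}.tsv")
            except ValueError as exc:
                log.warning("binned OR on %s skipped: %s", stat, exc)
        results["binned"] = binned

        stage = "inbreed"
        layout = (
            GenomeLayout.default(cfg.l_auto)
            if truth is None
            else GenomeLayout(results_layout_lengths(gm))
        )
        profiles = build_profiles(gm, segments, layout=layout, min_kb=cfg.min_kb)
        results["profiles"] = profiles
        write_profiles(profiles, summaries, out / "inbreeding.tsv")
        pc = per_chromosome_f(gm)
        write_per_chrom(pc["f1_matrix"], [s.id for s in gm.samples], out / "per_chrom_f1.tsv")
        results["per_chrom"] = pc
        try:
            results["correlations"] = measure_correlations(profiles, summaries)
        except ValueError:
            results["correlations"] = None

        stage = "assoc"
        k = min(cfg.n_pcs, gm.n_samples - 2)
        _, tags = ld_tag_groups(gm)
        first_of_group = np.zeros(gm.n_markers, dtype=bool)
        seen = set()
        for j, g in enumerate(tags):
            if g not in seen:
                first_of_group[j] = True
                seen.add(g)
        pcs = genotype_pca(gm, k=k, marker_index=np.where(first_of_group)[0]) if k >= 1 else None
        cov, names = build_covariates(gm, pcs, use_sex=cfg.use_sex, use_missing=cfg.use_missing)
        if cov is not None:  # drop constant covariates (e.g. zero missingness)
            keep = [j for j in range(cov.shape[1]) if np.ptp(cov[:, j]) > 0]
            cov = cov[:, keep] if keep else None
            names = [names[j] for j in keep]
        status = gm.case_mask.astype(float)
        assoc = {}
        measures = {
            "f1": np.array([p.f1 for p in profiles]),
            "f2": np.array([p.f2 for p in profiles]),
            "f3": np.array([p.f3 for p in profiles]),
            "f_roh": np.array([p.f_roh for p in profiles]),
        }
        for name, vec in measures.items():
            if np.ptp(vec[np.isfinite(vec)]) == 0:
                log.warning("assoc on %s skipped: measure is constant", name)
                continue
            res = logistic_glm(status, vec, cov, covariate_names=names)
            if cfg.n_perm >= 100:
                perm = perm_regressor_residuals(
                    status, vec, cov, n_perm=cfg.n_perm, seed=cfg.seed
                )
                res.perm_p = perm.perm_p
                res.n_perm = perm.n_perm
                res.seed = cfg.seed
            assoc[name] = res
        results["assoc"] = assoc
        _write_assoc(assoc, out / "assoc.tsv")

        stage = "report"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "inputs": {str(p): _sha256(p) for p in input_paths},
            "outputs": {
                p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (out / "report.txt").write_text(render_report(cfg, results))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    return results


def results_layout_lengths(gm: GenotypeMatrix):
    """A layout covering the observed chromosomes (simulated cohorts)."""
    chroms = gm.chroms
    positions = gm.positions
    lengths = []
    for c in range(1, int(chroms.max()) + 1):
        sel = chroms == c
        lengths.append(int(positions[sel].max()) + 1000 if sel.any() else 1)
    return tuple(lengths)


def _write_assoc(assoc: dict, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("measure\tcoef\tse\twald_p\tperm_p\tn_perm\tcovariates\n")
        for name, r in assoc.items():
            fh.write(
                f"{name}\t{r.coef:.6g}\t{r.se:.6g}\t{r.wald_p:.4g}\t{r.perm_p:.4g}"
                f"\t{r.n_perm}\t{','.join(r.covariates)}\n"
            )


def render_report(cfg: PipelineConfig, results: dict) -> str:
    gm = results["gm"]
    segments = results["segments"]
    lines = [
        "homburden pipeline report",
        "=" * 40,
        f"samples: {gm.n_samples} ({int(gm.case_mask.sum())} cases, "
        f"{int((~gm.case_mask).sum())} controls); markers: {gm.n_markers}",
        f"seed: {cfg.seed}",
        "",
        f"ROH segments (>= {cfg.min_snps} SNPs, >= {cfg.min_kb:.0f} kb): {len(segments)}",
    ]
    if segments:
        per_person = len(segments) / gm.n_samples
        lines.append(f"mean segments per person: {per_person:.2f}")
    lines.append("")
    lines.append("burden (cases vs controls):")
    for stat, res in results["burden_tests"].items():
        lines.append(
            f"  {stat}: mean_case={res['mean_case']:.4g} mean_control={res['mean_control']:.4g} "
            f"p={res['p']:.3g} perm_p={res['p_perm']:.3g}"
        )
    lines.append("")
    lines.append(f"recurrent pools (> {cfg.pool_min_members - 1} carriers, "
                 f">= {cfg.pool_min_kb:.0f} kb): {len(results['pools'])}")
    for p in results["pools"]:
        lines.append(
            f"  pool {p.pool_id}: chr{p.chrom}:{p.consensus_start_bp}-{p.consensus_end_bp} "
            f"({p.consensus_kb:.0f} kb, {p.n_case_carriers}/{p.n_control_carriers} "
            f"case/control carriers, chi2={p.chi2:.2f}, p={p.p_carrier:.3g})"
        )
    lines.append("")
    lines.append("inbreeding association (GLM):")
    for name, r in results["assoc"].items():
        lines.append(
            f"  {name}: coef={r.coef:.4g} se={r.se:.4g} wald_p={r.wald_p:.3g} "
            f"perm_p={r.perm_p:.3g}"
        )
    return "\n".join(lines) + "\n"
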