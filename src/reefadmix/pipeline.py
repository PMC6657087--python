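"""End-to-end orchestration of the SNP analysis stages.

Stage order is fixed: simulate (optional) -> filter -> convert ->
{distance, dstat, comphet} -> delimit-rank.  Every output TSV carries a
provenance header (package version, seed, config hash) so re-running with an
identical configuration reproduces identical non-stochastic outputs.  All
randomness flows from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import delimitation, distances, dstat, fixtures, snp_io
from .composition import base_composition, homogeneity_test
from .snp_io import FilterSpec
from .synthetic_data import SimulationConfig, emit_popmap, popmap, simulate_site_patterns

logger = logging.getLogger("reefadmix")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    vcf: str | None = None
    popmap: str | None = None
    alignment: str | None = None
    alignment_format: str = "fasta"
    groups: dict[str, str] | None = None
    models: str | None = None  # YAML path; None -> packaged fixture models
    use_count_fixture: bool = False
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    min_samples_locus: int = 10
    outgroup: str | None = None
    focal_p3: str | None = None
    alpha: float = 0.01
    mode: str = "strict"
    simulate: SimulationConfig | None = None
    boot_reps: int = 500
    reference_model: str = "A"
    comphet_sims: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.mode not in ("strict", "frequency"):
            raise ValueError("mode must be 'strict' or 'frequency'")
        for name in ("vcf", "popmap", "alignment", "models"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def count_quartets(n_taxa: int) -> int:
    """Number of distinct unrooted four-taxon subsets: C(n_taxa, 4)."""
    if n_taxa < 4:
        raise ValueError(f"need at least 4 taxa, got {n_taxa}")
    import math

    return math.comb(n_taxa, 4)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the configuration (key order independent)."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# reefadmix {__version__}\n")
        fh.write(f"# seed {cfg.seed}\n")
        fh.write(f"# config {config_hash(cfg)}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def _read_popmap(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, taxon = line.split("\t")[:2]
            out[sample] = taxon
    return out


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute the configured stages in dependency order.

    Returns a mapping from stage name to its primary output path.  A stage
    failure raises :class:`StageError` naming the stage.
    """
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    vcf_path = cfg.vcf
    popmap_path = cfg.popmap
    if cfg.simulate is not None:
        try:
            sim_cfg = cfg.simulate
            _, matrix = simulate_site_patterns(sim_cfg)
            vcf_path = str(out_dir / "simulated.vcf")
            popmap_path = str(out_dir / "simulated.popmap.tsv")
            snp_io.write_vcf(matrix, vcf_path)
            emit_popmap(popmap(sim_cfg), popmap_path)
            outputs["simulate"] = Path(vcf_path)
            logger.info("simulate: %d sites -> %s", matrix.n_sites, vcf_path)
        except Exception as exc:
            raise StageError(f"simulate: {exc}") from exc

    matrix = None
    if vcf_path is not None:
        try:
            matrix = snp_io.read_vcf(vcf_path)
            matrix, report = snp_io.filter_sites(matrix, cfg.filter_spec)
            outputs["filter"] = _write_tsv(
                report.to_frame(), out_dir / "filter_report.tsv", cfg
            )
            logger.info("filter: %d -> %d sites", report.n_in, report.n_out)
        except Exception as exc:
            raise StageError(f"filter: {exc}") from exc
        try:
            min_loc = min(cfg.min_samples_locus, matrix.n_samples)
            aln = snp_io.to_alignment(matrix, min_samples_locus=min_loc)
            aln_path = out_dir / "converted.fasta"
            snp_io.write_alignment(aln, aln_path, "fasta")
            outputs["convert"] = aln_path
        except Exception as exc:
            raise StageError(f"convert: {exc}") from exc

    alignment = None
    if cfg.alignment is not None:
        from .alignment import read_alignment

        alignment = read_alignment(cfg.alignment, cfg.alignment_format)

    if alignment is not None and cfg.groups is not None:
        try:
            gd = distances.group_distances(alignment, cfg.groups)
            rows = [
                {"kind": "within", "a": g, "b": g, "estimate": v}
                for g, v in gd.within.items()
            ]
            rows += [
                {"kind": "between", "a": g1, "b": g2, "estimate": v}
                for (g1, g2), v in gd.between.items()
            ]
            rows += [
                {"kind": "net", "a": g1, "b": g2, "estimate": v}
                for (g1, g2), v in gd.net.items()
            ]
            outputs["distance"] = _write_tsv(
                pd.DataFrame(rows), out_dir / "distances.tsv", cfg
            )
        except Exception as exc:
            raise StageError(f"distance: {exc}") from exc

    try:
        report_df = None
        if cfg.use_count_fixture:
            counts = fixtures.load_abba_baba_counts()
            report_df = dstat.run_all(
                counts[["id", "p1", "p2", "p3", "outgroup", "n_abba", "n_baba"]],
                alpha=cfg.alpha,
            )
        elif matrix is not None and popmap_path is not None and cfg.outgroup:
            pm = _read_popmap(popmap_path)
            ingroup = [s for s in matrix.sample_ids if pm.get(s) != cfg.outgroup]
            out_samples = [s for s in matrix.sample_ids if pm.get(s) == cfg.outgroup]
            if not out_samples:
                raise ValueError(f"no sample maps to outgroup {cfg.outgroup!r}")
            hyps = dstat.enumerate_hypotheses(
                ingroup, out_samples[0], focal_p3=cfg.focal_p3
            )
            report_df = dstat.run_all(
                matrix, hyps, alpha=cfg.alpha, mode=cfg.mode
            )
        if report_df is not None:
            outputs["dstat"] = _write_tsv(
                report_df, out_dir / "dstat_report.tsv", cfg
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"dstat: {exc}") from exc

    if alignment is not None:
        try:
            table = base_composition(alignment)
            res = homogeneity_test(table, n_sims=cfg.comphet_sims, seed=cfg.seed)
            comp = table.copy()
            comp.insert(0, "taxon", comp.index)
            outputs["comphet_table"] = _write_tsv(
                comp.reset_index(drop=True), out_dir / "composition.tsv", cfg
            )
            summary = pd.DataFrame(
                [
                    {
                        "chi2": res.chi2,
                        "df": res.df,
                        "p_analytic": res.p_analytic,
                        "p_simulated": res.p_simulated,
                        "n_sims": res.n_sims,
                    }
                ]
            )
            outputs["comphet"] = _write_tsv(
                summary, out_dir / "comphet.tsv", cfg
            )
        except Exception as exc:
            raise StageError(f"comphet: {exc}") from exc

    try:
        if cfg.models is not None:
            models = delimitation.load_models_yaml(cfg.models)
        else:
            models = delimitation.load_partition_fixtures()
        comps = delimitation.rank_models(models, cfg.reference_model)
        outputs["delimit"] = _write_tsv(
            delimitation.comparisons_to_frame(models, comps),
            out_dir / "delimitation_report.tsv",
            cfg,
        )
    except Exception as exc:
        raise StageError(f"delimit-rank: {exc}") from exc

    return outputs
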