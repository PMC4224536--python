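"""End-to-end pipeline: data -> diversity -> theta posteriors -> ratio.

The pipeline runs in one of three modes:

* ``synthetic`` -- simulate a dataset from a :class:`SimConfig`, then
  analyse it;
* ``files`` -- analyse an existing FASTA alignment + genotype TSV;
* ``priors-only`` -- skip the data stages and propagate explicit prior
  bounds (replication of the published computation).

Unless explicit theta priors are given, the uniform theta priors for the
ratio stage are the empirical 95% credible intervals of the two theta
posteriors, optionally snapped to a coarse rounding grid
(``round_priors``).  Everything is deterministic under the global seed.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .datatypes import GenotypeMatrix, SequenceAlignment
from .diversity import summarize_diversity
from .io import read_fasta, read_genotypes, write_fasta, write_genotypes, write_trace
from .ratio import PriorSpec, sample_ratio_posterior, summarize
from .simulate import SimConfig, simulate_dataset
from .theta import McmcOptions, bayes_theta_microsatellites, bayes_theta_sequences

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "round_prior_bounds",
    "validate_report",
    "load_config",
]

logger = logging.getLogger("neratio")

_SCHEMA_PATH = Path(__file__).parent / "report_schema.json"


class SyntheticSection(BaseModel):
    n_tips: int = 18
    L: int = 512
    theta_seq: float = 0.008
    R: float = 33.0
    n_individuals: int = 96
    n_loci: int = 7
    theta_msat: float = 4.875
    ancestral_size: int = 20


class InputSection(BaseModel):
    fasta: str
    genotypes: str


class McmcSection(BaseModel):
    burn_in: int = 500
    n_samples: int = 1500
    thin: int = 1
    tree_moves_per_sweep: int = 8
    topo_move_prob: float = 0.3


class PriorSection(BaseModel):
    source: Literal["from-theta-posteriors", "explicit"] = "from-theta-posteriors"
    round_priors: bool = False
    theta_n: Optional[tuple[float, float]] = None
    theta_m: Optional[tuple[float, float]] = None
    mu_n: tuple[float, float] = (1e-5, 1e-3)
    mu_m: tuple[float, float] = (1e-8, 1e-7)
    theta_seq_prior: tuple[float, float] = (0.0, 0.1)
    theta_msat_prior: tuple[float, float] = (0.0, 100.0)


class RatioSection(BaseModel):
    n_samples: int = 1_000_000
    mode: Literal["published", "adjusted"] = "published"
    generation_time: float = 3.0


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    seed: int
    mode: Literal["synthetic", "files", "priors-only"]
    synthetic: Optional[SyntheticSection] = None
    inputs: Optional[InputSection] = None
    mcmc: McmcSection = Field(default_factory=McmcSection)
    priors: PriorSection = Field(default_factory=PriorSection)
    ratio: RatioSection = Field(default_factory=RatioSection)
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_mode(self):
        if self.mode == "synthetic" and self.inputs is not None:
            raise ValueError("synthetic mode must not set real inputs")
        if self.mode == "files":
            if self.inputs is None:
                raise ValueError("files mode requires an inputs section")
            if self.synthetic is not None:
                raise ValueError("files mode must not set a synthetic section")
        if self.mode == "priors-only":
            if self.priors.source != "explicit":
                raise ValueError("priors-only mode requires explicit priors")
        if self.priors.source == "explicit":
            if self.priors.theta_n is None or self.priors.theta_m is None:
                raise ValueError("explicit priors require theta_n and theta_m bounds")
        return self


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)


def round_prior_bounds(lo: float, hi: float) -> tuple[float, float]:
    """Snap prior bounds to the nearest half-decade grid of the range span.

    The grid step is 0.5 * 10^floor(log10(hi - lo)); e.g. (10.2, 16.6)
    snaps to (10.0, 16.5) and (0.012, 0.048) to (0.01, 0.05).
    """
    span = hi - lo
    if span <= 0:
        return lo, hi
    g = 0.5 * 10.0 ** math.floor(math.log10(span))
    return round(lo / g) * g, round(hi / g) * g


def _mcmc_options(section: McmcSection, seed: int) -> McmcOptions:
    return McmcOptions(
        burn_in=section.burn_in,
        n_samples=section.n_samples,
        thin=section.thin,
        tree_moves_per_sweep=section.tree_moves_per_sweep,
        topo_move_prob=section.topo_move_prob,
        seed=seed,
    )


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the configured stages and return (and optionally write) the
    report bundle.  When ``out_dir`` is given, writes ``report.json``,
    ``report.txt``, data files and posterior traces under it."""
    logging.basicConfig(level=config.log_level)
    seeds = np.random.SeedSequence(config.seed)
    s_data, s_seq, s_msat, s_ratio = [int(s.generate_state(1)[0]) for s in seeds.spawn(4)]

    report: dict = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "stage_seeds": {
            "data": s_data,
            "theta_seq": s_seq,
            "theta_msat": s_msat,
            "ratio": s_ratio,
        },
        "diversity": None,
        "theta_seq": None,
        "theta_msat": None,
    }

    alignment: SequenceAlignment | None = None
    genotypes: GenotypeMatrix | None = None
    if config.mode == "synthetic":
        sim = config.synthetic or SyntheticSection()
        sim_config = SimConfig(seed=s_data, **sim.model_dump())
        logger.info("simulating synthetic dataset (seed %d)", s_data)
        alignment, genotypes = simulate_dataset(sim_config)
    elif config.mode == "files":
        logger.info("reading %s and %s", config.inputs.fasta, config.inputs.genotypes)
        alignment = read_fasta(config.inputs.fasta)
        genotypes = read_genotypes(config.inputs.genotypes)

    theta_seq_post = theta_msat_post = None
    if alignment is not None:
        logger.info("diversity indices")
        report["diversity"] = summarize_diversity(alignment, genotypes).to_dict()
        logger.info("sequence theta MCMC")
        theta_seq_post = bayes_theta_sequences(
            alignment,
            prior_bounds=config.priors.theta_seq_prior,
            options=_mcmc_options(config.mcmc, s_seq),
        )
        report["theta_seq"] = theta_seq_post.to_dict()
        logger.info(
            "theta_seq mean %.4g, acceptance %s",
            theta_seq_post.mean,
            theta_seq_post.acceptance,
        )
        logger.info("microsatellite theta MCMC")
        theta_msat_post = bayes_theta_microsatellites(
            genotypes,
            prior_bounds=config.priors.theta_msat_prior,
            options=_mcmc_options(config.mcmc, s_msat),
        )
        report["theta_msat"] = theta_msat_post.to_dict()
        logger.info(
            "theta_msat mean %.4g, acceptance %s",
            theta_msat_post.mean,
            theta_msat_post.acceptance,
        )

    if config.priors.source == "explicit":
        theta_n_bounds = tuple(config.priors.theta_n)
        theta_m_bounds = tuple(config.priors.theta_m)
    else:
        theta_n_bounds = theta_msat_post.ci95
        theta_m_bounds = theta_seq_post.ci95
    rounded = False
    if config.priors.round_priors:
        theta_n_bounds = round_prior_bounds(*theta_n_bounds)
        theta_m_bounds = round_prior_bounds(*theta_m_bounds)
        rounded = True

    priors = PriorSpec(
        theta_n=theta_n_bounds,
        theta_m=theta_m_bounds,
        mu_n=tuple(config.priors.mu_n),
        mu_m=tuple(config.priors.mu_m),
        generation_time=config.ratio.generation_time,
    )
    report["priors_used"] = {
        **priors.to_dict(),
        "source": config.priors.source,
        "rounded": rounded,
    }
    # the published theta_m is per site while mu_m is per locus; the default
    # mode reproduces the published computation as printed
    report["unit_note"] = (
        "theta_m from sequence data is per site while mu_m is per locus "
        "(per year as published); mode='published' combines them as printed, "
        "mode='adjusted' additionally converts mu_m to per-generation units."
    )

    logger.info("ratio Monte-Carlo (%d draws)", config.ratio.n_samples)
    posterior = sample_ratio_posterior(
        priors,
        n_samples=config.ratio.n_samples,
        seed=s_ratio,
        mode=config.ratio.mode,
    )
    report["ratio"] = summarize(posterior).to_dict()

    validate_report(report)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if alignment is not None and config.mode == "synthetic":
            write_fasta(alignment, out / "sequences.fasta")
            write_genotypes(genotypes, out / "genotypes.tsv")
        if theta_seq_post is not None:
            write_trace(theta_seq_post.samples, out / "traces" / "theta_seq.tsv")
            write_trace(theta_msat_post.samples, out / "traces" / "theta_msat.tsv")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "report.txt").write_text(render_text_report(report))
        logger.info("report written to %s", out)
    return report


def render_text_report(report: dict) -> str:
    lines = ["neratio pipeline report", "=======================", ""]
    lines.append(f"global seed: {report['seed']}")
    lines.append(f"mode: {report['config']['mode']}")
    if report.get("diversity"):
        d = report["diversity"]
        if d.get("heterozygosity"):
            h = d["heterozygosity"]
            lines.append(
                f"Hexp mean {h['mean']:.3f} (range {h['range'][0]:.3f}-{h['range'][1]:.3f})"
            )
        if d.get("haplotype_diversity"):
            hs, sd = d["haplotype_diversity"]
            lines.append(f"Hs {hs:.3f} +/- {sd:.3f}")
        if d.get("nucleotide_diversity"):
            pi, sd = d["nucleotide_diversity"]
            lines.append(f"pi/site {pi:.4f} +/- {sd:.4f}")
    for key in ("theta_seq", "theta_msat"):
        if report.get(key):
            t = report[key]
            lines.append(
                f"{key}: mean {t['mean']:.4g}, mode {t['mode']:.4g}, "
                f"95% CI ({t['ci95'][0]:.4g}, {t['ci95'][1]:.4g}), ESS {t['ess']:.0f}"
            )
    p = report["priors_used"]
    lines.append(
        f"priors ({p['source']}{', rounded' if p['rounded'] else ''}): "
        f"theta_n {p['theta_n']}, theta_m {p['theta_m']}, "
        f"mu_n {p['mu_n']}, mu_m {p['mu_m']}"
    )
    r = report["ratio"]
    lines.append(
        f"Ne:Nef = {r['mean']:.3f} (SD {r['sd']:.3f}, "
        f"95% CI {r['ci95'][0]:.3f}-{r['ci95'][1]:.3f})"
    )
    lines.append(
        f"reduction vs ideal (Ne:Nef = 2): {r['reduction_mean_pct']}% "
        f"(range {r['reduction_range_pct'][0]}-{r['reduction_range_pct'][1]}%)"
    )
    lines.append("")
    lines.append(report["unit_note"])
    return "\n".join(lines) + "\n"


def validate_report(report: dict) -> None:
    """Check the report against the bundled JSON schema (minimal checker:
    type / required / properties / items)."""
    schema = json.loads(_SCHEMA_PATH.read_text())
    _check(report, schema, "report")


_TYPES = {
    "object": dict,
    "array": (list, tuple),
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


def _check(value, schema: dict, where: str) -> None:
    t = schema.get("type")
    if t is not None:
        types = t if isinstance(t, list) else [t]
        if not any(isinstance(value, _TYPES[x]) for x in types):
            raise ValueError(f"report schema violation at {where}: expected {t}")
        if isinstance(value, bool) and "boolean" not in types:
            raise ValueError(f"report schema violation at {where}: expected {t}")
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                raise ValueError(f"report schema violation at {where}: missing {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _check(value[key], sub, f"{where}.{key}")
    if isinstance(value, (list, tuple)) and "items" in schema:
        for k, item in enumerate(value):
            _check(item, schema["items"], f"{where}[{k}]")
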