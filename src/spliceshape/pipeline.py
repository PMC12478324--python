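"""Whole-analysis orchestration: junction tables in, shape fit and reports out.

``run`` chains the stages — parse, merge, filter, strand assignment,
donor- and acceptor-anchored grouping, median frequency matrices, grid fit
of the Weibull shape, efficiency indices, divergence and detectability
summaries — and writes every result as headered TSV/JSON into the output
directory, with a run log recording the seed and library versions.
"""

from __future__ import annotations

import json
import logging
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from . import junctions as jio
from . import sites as asites
from . import weibull as wb
from .divergence import kld_from_samples
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)

ROLES = (jio.DONOR, jio.ACCEPTOR)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    """Settings of one pipeline run.

    Either ``sj_paths`` + ``gtf_path`` (real data) or ``synthetic`` must be
    given.  ``reps`` is the Monte Carlo repetition count per multiplicity in
    the grid fit; ``min_kld_groups`` is the smallest stratum size for which
    a KLd entry is reported (divergence estimates from a handful of groups
    are meaningless).
    """

    sj_paths: Sequence[Union[str, Path]] = ()
    gtf_path: Optional[Union[str, Path]] = None
    synthetic: Optional[SyntheticConfig] = None
    out_dir: Union[str, Path] = "spliceshape_out"
    min_samples: int = 3
    min_overhang: int = 0
    Kmax: int = asites.DEFAULT_KMAX
    Mmax: int = asites.DEFAULT_MMAX
    grid_start: float = 0.01
    grid_stop: float = 0.99
    grid_step: float = 0.01
    reps: int = 10_000
    detect_cutoff: float = 0.002
    kld_bins: int = 50
    min_kld_groups: int = 50
    seed: int = 0
    make_figures: bool = False

    def validate(self) -> None:
        if self.synthetic is None:
            if not self.sj_paths:
                raise PipelineError("config: no SJ tables and no synthetic config")
            if self.gtf_path is None:
                raise PipelineError("config: a GTF path is required for real input")
            for p in list(self.sj_paths) + [self.gtf_path]:
                if not Path(p).exists():
                    raise PipelineError(f"config: input not found: {p}")
        if self.min_samples < 1:
            raise PipelineError("config: min_samples must be >= 1")
        if not 0 <= self.detect_cutoff < 1:
            raise PipelineError("config: detect_cutoff must lie in [0, 1)")

    def grid(self) -> np.ndarray:
        return wb.default_grid(self.grid_start, self.grid_stop, self.grid_step)


@dataclass
class RoleResult:
    """Per-anchor-role outputs (donor-anchored or acceptor-anchored)."""

    role: str
    n_groups: int
    histogram: dict[int, int]
    mf: asites.MedianFrequencyMatrix
    fit: wb.ShapeFit
    efficiency: float


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc: dict
    roles: dict[str, RoleResult]
    joint_efficacy: float
    kld_table: pd.DataFrame
    detect_table: pd.DataFrame
    out_dir: Path


def _stage_seed(seed: int, label: str) -> np.random.Generator:
    # stable per-stage fan-out of the single run seed
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=tuple(label.encode()))
    )


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Creates ``config.out_dir`` (removed again if a stage fails, so no
    partial bundle is left behind) and returns the in-memory result.
    Identical configs produce identical numeric outputs.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("spliceshape")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info(
            "spliceshape %s | numpy %s pandas %s | seed %d",
            __version__, np.__version__, pd.__version__, config.seed,
        )
        return _run_stages(config, out_dir)
    except Exception as exc:
        handler.close()
        root.removeHandler(handler)
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"pipeline failed: {exc}") from exc
    finally:
        if handler in root.handlers:
            handler.close()
            root.removeHandler(handler)


def _run_stages(config: PipelineConfig, out_dir: Path) -> PipelineResult:
    # --- input stage ------------------------------------------------------
    if config.synthetic is not None:
        logger.info("generating synthetic dataset (a_true=%g)", config.synthetic.a_true)
        ds = generate(config.synthetic, out_dir / "synthetic")
        sj_paths, gtf_path = ds.sj_paths, ds.gtf_path
    else:
        sj_paths = [Path(p) for p in config.sj_paths]
        gtf_path = Path(config.gtf_path)

    try:
        tables = [jio.parse_sj_tab(p) for p in sj_paths]
    except jio.SJParseError as exc:
        raise PipelineError(f"parse: {exc}") from exc
    n_parsed = sum(len(t) for t in tables)

    merged = jio.merge_samples(tables)
    merged = jio.filter_min_overhang(merged, config.min_overhang)
    kept = jio.filter_min_samples(merged, config.min_samples)
    try:
        stranded, strand_report = jio.assign_strand(kept, gtf_path)
    except jio.AnnotationError as exc:
        raise PipelineError(f"strand assignment: {exc}") from exc

    n_overhang20 = sum(1 for j in stranded if j.max_overhang > 20)
    qc = {
        "n_samples": len(sj_paths),
        "n_junction_records": n_parsed,
        "n_merged": len(merged),
        "n_after_min_samples": len(kept),
        "n_stranded": strand_report.retained,
        "n_intergenic": strand_report.intergenic,
        "n_conflicting_strand": strand_report.conflicting,
        "n_star_strand_disagreements": strand_report.star_disagreements,
        "frac_overhang_gt20": (n_overhang20 / len(stranded)) if stranded else float("nan"),
    }
    logger.info("QC: %s", qc)
    (out_dir / "qc.json").write_text(json.dumps(qc, indent=1))
    jio.write_sj_tab(stranded, out_dir / "junctions.filtered.tab", extra_columns=True)

    # --- per-role analysis ------------------------------------------------
    roles: dict[str, RoleResult] = {}
    kld_rows = []
    for role in ROLES:
        groups = asites.group_by_anchor(stranded, role)
        hist = asites.multiplicity_histogram(groups, config.Mmax)
        mf = asites.median_frequency_matrix(groups, config.Kmax, config.Mmax)
        mf.to_tsv(out_dir / f"mf.{role}.tsv")
        fit = wb.fit_shape(
            mf, grid=config.grid(), reps=config.reps,
            seed=config.seed + (0 if role == jio.DONOR else 1),
        )
        fit.to_json(out_dir / f"fit.{role}.json")
        eff = wb.splicing_efficiency(fit.a_hat)
        logger.info("%s-anchored fit: a_hat=%.2f efficiency=%.2f (%d groups)",
                    role, fit.a_hat, eff, len(groups))
        roles[role] = RoleResult(
            role=role, n_groups=len(groups), histogram=hist,
            mf=mf, fit=fit, efficiency=eff,
        )

        # KLd of observed f(k,M) distributions vs the fitted model, per stratum
        samples = asites.frequency_samples(groups, config.Mmax)
        sim_cache: dict[int, np.ndarray] = {}
        for (k, M), obs in sorted(samples.items()):
            if obs.size < config.min_kld_groups:
                continue
            if M not in sim_cache:
                sim_cache[M] = wb.simulate_frequency_samples(
                    fit.a_hat, M, reps=max(config.reps, 2000),
                    rng=_stage_seed(config.seed, f"kld-{role}-{M}"),
                )
            div = kld_from_samples(obs, sim_cache[M][:, k - 1], n_bins=config.kld_bins)
            kld_rows.append({"role": role, "k": k, "M": M,
                             "n_groups": obs.size, "kld": div})

        # multiplicity histogram + heatmap tables
        pd.DataFrame(
            {"M": list(hist.keys()), "n_groups": list(hist.values())}
        ).to_csv(out_dir / f"multiplicity.{role}.tsv", sep="\t", index=False)

    heat = asites.junction_multiplicity_heatmap(stranded, config.Mmax)
    pd.DataFrame(
        heat,
        index=[f"numA{m}" for m in range(1, config.Mmax + 1)],
        columns=[f"numD{m}" for m in range(1, config.Mmax + 1)],
    ).to_csv(out_dir / "multiplicity_heatmap.tsv", sep="\t")

    kld_table = pd.DataFrame(kld_rows, columns=["role", "k", "M", "n_groups", "kld"])
    kld_table.to_csv(out_dir / "kld.tsv", sep="\t", index=False)

    # --- cross-role summaries --------------------------------------------
    joint = wb.joint_efficacy(
        roles[jio.DONOR].efficiency, roles[jio.ACCEPTOR].efficiency
    )
    detect_rows = []
    a_ref = roles[jio.DONOR].fit.a_hat
    for M in range(1, config.Mmax + 1):
        summ = wb.detect_counts(
            a_ref, M, cutoff=config.detect_cutoff,
            reps=max(config.reps, 2000),
            rng=_stage_seed(config.seed, f"detect-{M}"),
        )
        q25, q50, q75 = summ.quantiles()
        detect_rows.append({"M": M, "mean_detected": summ.mean,
                            "q25": q25, "median": q50, "q75": q75})
    detect_table = pd.DataFrame(detect_rows)
    detect_table.to_csv(out_dir / "detectability.tsv", sep="\t", index=False)

    # scaled-density comparison: empirical pooled scaled values vs model draws
    _write_scaled_density(config, roles, stranded, out_dir)

    summary = {
        "a_hat": {r: roles[r].fit.a_hat for r in ROLES},
        "efficiency": {r: roles[r].efficiency for r in ROLES},
        "joint_efficacy": joint,
        "seed": config.seed,
        "reps": config.reps,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    logger.info("joint efficacy (donor x acceptor): %.4f", joint)

    result = PipelineResult(
        config=config, qc=qc, roles=roles, joint_efficacy=joint,
        kld_table=kld_table, detect_table=detect_table, out_dir=out_dir,
    )
    if config.make_figures:
        _make_figures(result)
    return result


def _write_scaled_density(config, roles, stranded, out_dir) -> None:
    edges = np.linspace(0.0, 5.0, 101)
    rows = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for role in ROLES:
        groups = asites.group_by_anchor(stranded, role)
        pooled = asites.pooled_scaled_expression(groups)
        hist = np.histogram(np.clip(pooled, 0, 5), bins=edges)[0]
        rows[f"density_{role}"] = hist / max(hist.sum(), 1) / np.diff(edges)
        mhist = {
            M: c for M, c in roles[role].histogram.items()
            if 1 <= M <= config.Mmax and c > 0
        }
        if mhist:
            sim = wb.simulate_scaled_density(
                roles[role].fit.a_hat, mhist, reps=1,
                rng=_stage_seed(config.seed, f"density-{role}"),
            )
            shist = np.histogram(np.clip(sim, 0, 5), bins=edges)[0]
            rows[f"density_sim_{role}"] = shist / max(shist.sum(), 1) / np.diff(edges)
    pd.DataFrame(rows).to_csv(out_dir / "scaled_density.tsv", sep="\t", index=False)


def _make_figures(result: PipelineResult) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for role, rr in result.roles.items():
        ax.plot(rr.fit.grid, rr.fit.distances, label=f"{role}-anchored")
        ax.axvline(rr.fit.a_hat, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("shape parameter a")
    ax.set_ylabel("Euclidean distance of mf(k,M)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(result.out_dir / "distance_curve.png", dpi=150)
    plt.close(fig)

    dens = pd.read_csv(result.out_dir / "scaled_density.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(5, 4))
    mid = (dens["bin_left"] + dens["bin_right"]) / 2
    for col in dens.columns:
        if col.startswith("density"):
            ax.plot(mid, dens[col], label=col.replace("density_", ""))
    ax.set_xlabel("scaled expression level")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(result.out_dir / "scaled_density.png", dpi=150)
    plt.close(fig)
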