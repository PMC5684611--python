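"""Configuration-driven orchestration of the three-stage workflow.

Stage 1 (design of the experiment): build or load a phantom and evaluate the
forward solver at the quasi-random orientation design, reducing each field
solution to the per-tissue E^99th.  Stage 2 (polynomial chaos procedure):
fit the sparse Legendre surrogate per tissue and validate it by the
leave-one-out loop.  Stage 3 (analysis of the exposure): sample each
surrogate at many orientations and report distribution statistics, Sobol
indices and high-exposure orientation patterns.

Everything is deterministic for a fixed configuration: designs come from
the unscrambled Sobol sequence, the solver is iterative but seeded by
zeros, and no wall-clock values enter any output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    ANALYSIS_OFFSET,
    high_exposure_orientations,
    mean_stochastic_model,
    patterns_table,
    sample_exposure,
    sobol_indices,
    summarize_exposure,
)
from .chaos import PolynomialChaosResults
from .design import sobol_design
from .metrics import cns_aggregate, cube_average, tissue_E99
from .phantoms import (
    ChildPhantomSpec,
    VoxelPhantom,
    build_child_phantom,
    build_homogeneous_ellipsoid,
    build_homogeneous_sphere,
    read_phantom,
    write_phantom,
)
from .solver import UniformFieldSource, solve_scalar_potential
from .validation import AdaptiveFitTrace, adaptive_fit

__all__ = ["RunConfig", "ConfigError", "make_e99_forward", "run_pipeline", "run_mean_model"]

TABLE_HEADER = (
    "# units: V/m (RMS); B treated as RMS flux density; "
    "vector cube-average then magnitude; linear-interpolation percentiles\n"
)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Echoed verbatim into every run's metadata."""

    # phantom: either a builder spec or a path stem of a stored phantom
    phantom_kind: str = "sphere"  # sphere | ellipsoid | child | file
    phantom_path: str | None = None
    radius_m: float = 0.05
    semi_axes_m: tuple[float, float, float] = (0.04, 0.05, 0.058)
    sigma: float = 0.1
    voxel_size_m: float = 0.002
    child_spec: dict = field(default_factory=dict)
    seed: int = 0
    # source
    frequency_Hz: float = 50.0
    B_rms_T: float = 200e-6
    # solver
    solver_tol: float = 1e-8
    # metric
    cube_side_m: float = 0.002
    # surrogate / validation
    degree: int = 5
    pmse_threshold: float = 5.0
    n_cap: int = 200
    design_offset: int = 0
    # analysis
    n_samples: int = 10000
    analysis_offset: int = ANALYSIS_OFFSET
    pattern_fraction: float = 0.9
    # outputs
    out_dir: str = "run"

    def validate(self) -> None:
        if self.pmse_threshold <= 0:
            raise ConfigError("pmse_threshold must be positive")
        if self.phantom_kind not in ("sphere", "ellipsoid", "child", "file"):
            raise ConfigError(f"unknown phantom kind {self.phantom_kind!r}")
        if self.phantom_kind == "file":
            if not self.phantom_path:
                raise ConfigError("phantom_kind 'file' requires phantom_path")
            stem = Path(self.phantom_path)
            if not stem.with_suffix(".hdr.yaml").exists():
                raise ConfigError(f"phantom header not found at {stem}.hdr.yaml")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        if isinstance(cfg.semi_axes_m, list):
            cfg.semi_axes_m = tuple(cfg.semi_axes_m)
        cfg.validate()
        return cfg


def build_phantom(config: RunConfig) -> VoxelPhantom:
    config.validate()
    if config.phantom_kind == "sphere":
        return build_homogeneous_sphere(config.radius_m, config.sigma, config.voxel_size_m)
    if config.phantom_kind == "ellipsoid":
        return build_homogeneous_ellipsoid(config.semi_axes_m, config.sigma, config.voxel_size_m)
    if config.phantom_kind == "child":
        spec = ChildPhantomSpec(**config.child_spec) if config.child_spec else ChildPhantomSpec(
            voxel_size_m=config.voxel_size_m
        )
        return build_child_phantom(spec, seed=config.seed)
    return read_phantom(config.phantom_path)


def make_e99_forward(
    phantom: VoxelPhantom,
    label: int | None = None,
    frequency_Hz: float = 50.0,
    B_rms_T: float = 200e-6,
    tol: float = 1e-8,
    cube_side_m: float = 0.002,
    log=None,
):
    """Forward evaluator orientation -> E^99th for one tissue (or whole CNS).

    The returned callable is what the adaptive fitting loop consumes; it
    solves the scalar-potential system at the requested orientation and
    reduces the field to the tissue metric.
    """
    side = max(cube_side_m, phantom.voxel_size_m)

    def forward(theta_deg: float, phi_deg: float) -> float:
        src = UniformFieldSource(frequency_Hz, B_rms_T, theta_deg, phi_deg)
        sol = solve_scalar_potential(phantom, src, tol=tol)
        if log is not None:
            log(
                f"solve theta={theta_deg:8.3f} phi={phi_deg:9.3f} "
                f"iters={sol.iterations:5d} residual={sol.residual:.2e}"
            )
        avg = cube_average(sol, phantom, side)
        if label is None:
            exps = [tissue_E99(avg, phantom, l) for l in phantom.tissue_labels()]
            return cns_aggregate(exps, phantom)
        return tissue_E99(avg, phantom, label).E99th_V_per_m

    return forward


def _write_table(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(TABLE_HEADER)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig, echo=None) -> Path:
    """Execute design -> surrogate -> analysis for every reportable tissue.

    Writes, under ``config.out_dir``: the phantom, per-tissue observation and
    validation tables, serialized surrogates, summary / sensitivity / pattern
    tables and a metadata echo.  Returns the run directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)
        if echo:
            echo(msg)

    stage = "phantom"
    try:
        phantom = build_phantom(config)
        write_phantom(phantom, out / "phantom")

        stage = "surrogate"
        by_label = phantom.tissue_by_label
        report_labels = [
            (l, by_label[l].name)
            for l in phantom.tissue_labels()
            if by_label[l].group in ("CNS", "PNS")
        ]
        summaries, sens_rows, pat_frames, val_rows = [], [], [], []
        observations: dict[str, np.ndarray] = {}
        n_design_max = 0
        for label, name in report_labels:
            forward = make_e99_forward(
                phantom,
                label,
                config.frequency_Hz,
                config.B_rms_T,
                config.solver_tol,
                config.cube_side_m,
                log=log,
            )
            trace = AdaptiveFitTrace()
            res, report, design = adaptive_fit(
                forward,
                threshold=config.pmse_threshold,
                p0=config.degree,
                n_cap=config.n_cap,
                offset=config.design_offset,
                trace=trace,
            )
            n_design_max = max(n_design_max, design.n)
            observations[name] = np.asarray(res.model.endog, dtype=float)
            res.save(out / f"surrogate_{name}.yaml")
            for s in trace.steps:
                val_rows.append({"tissue": name, **s})

            stage = "analysis"
            pred = sample_exposure(res, config.n_samples, config.analysis_offset)
            summaries.append(summarize_exposure(pred, name))
            sens = sobol_indices(res)
            sens_rows.append(
                {"tissue": name, "s_theta": sens.s_theta, "s_phi": sens.s_phi}
            )
            pats = high_exposure_orientations(
                res, config.n_samples, config.pattern_fraction, config.analysis_offset
            )
            pat_frames.append(patterns_table(pats, name))
            stage = "surrogate"

        stage = "outputs"
        _write_table(
            pd.DataFrame([asdict(s) for s in summaries]), out / "exposure_summary.tsv"
        )
        _write_table(pd.DataFrame(sens_rows), out / "sensitivity.tsv")
        _write_table(
            pd.concat(pat_frames, ignore_index=True)
            if pat_frames
            else pd.DataFrame(),
            out / "patterns.tsv",
        )
        _write_table(pd.DataFrame(val_rows), out / "validation_trace.tsv")
        # designs are nested (shared Sobol offset): pad to the longest one
        obs = sobol_design(n_design_max, config.design_offset).to_frame()
        for name, y in observations.items():
            col = np.full(n_design_max, np.nan)
            col[: y.size] = y
            obs[name] = col
        _write_table(obs, out / "observations.tsv")
        (out / "solve_log.txt").write_text("\n".join(log_lines) + "\n")
        meta = {
            "package": "elfdosim",
            "version": __version__,
            "config": asdict(config),
            "conventions": {
                "B_amplitude": "RMS",
                "E_values": "RMS, V/m",
                "cube_average": "vector mean then magnitude, tissue-restricted sliding cube",
                "percentile": "linear interpolation",
                "axes": "z vertical (TOP), x anteroposterior (FRONT), y mediolateral (LAT)",
            },
        }
        (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))
        return out
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc


def run_mean_model(run_dirs: list[str | Path], out_dir: str | Path, config: RunConfig | None = None) -> Path:
    """Mean stochastic model over K completed runs sharing one design.

    Averages, per tissue present in every run, the observation vectors, then
    applies the standard fit + validation + analysis pipeline to the mean.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = [
        pd.read_csv(Path(d) / "observations.tsv", sep="\t", comment="#") for d in run_dirs
    ]
    if not tables:
        raise ValueError("need at least one run directory")
    n = len(tables[0])
    if any(len(t) != n for t in tables):
        raise ValueError("runs do not share one experimental design")
    for t in tables[1:]:
        if not np.allclose(
            t[["theta_deg", "phi_deg"]].to_numpy(),
            tables[0][["theta_deg", "phi_deg"]].to_numpy(),
        ):
            raise ValueError("runs do not share one experimental design")
    tissue_cols = [c for c in tables[0].columns if c not in ("theta_deg", "phi_deg")]
    common = [c for c in tissue_cols if all(c in t.columns for t in tables)]
    if not common:
        raise ValueError("no tissue common to all runs")

    summaries, sens_rows, pat_frames, val_rows = [], [], [], []
    for name in common:
        sets = [t[name].to_numpy() for t in tables]
        # designs are nested: use the prefix where every run has observations
        n_valid = min(int(np.sum(np.isfinite(y))) for y in sets)
        if n_valid < 3:
            raise ValueError(f"tissue {name!r}: too few shared observations")
        design = sobol_design(n_valid, config.design_offset)
        sets = [y[:n_valid] for y in sets]
        res, report = mean_stochastic_model(sets, design, config.degree, config.pmse_threshold)
        res.save(out / f"surrogate_{name}.yaml")
        val_rows.append(
            {
                "tissue": name,
                "n": report.n,
                "p": report.p,
                "pmse_percent": report.pmse_percent,
                "accepted": report.accepted,
            }
        )
        pred = sample_exposure(res, config.n_samples, config.analysis_offset)
        summaries.append(summarize_exposure(pred, name))
        s = sobol_indices(res)
        sens_rows.append({"tissue": name, "s_theta": s.s_theta, "s_phi": s.s_phi})
        pat_frames.append(
            patterns_table(
                high_exposure_orientations(
                    res, config.n_samples, config.pattern_fraction, config.analysis_offset
                ),
                name,
            )
        )
    _write_table(pd.DataFrame([asdict(s) for s in summaries]), out / "exposure_summary_mean.tsv")
    _write_table(pd.DataFrame(sens_rows), out / "sensitivity_mean.tsv")
    _write_table(pd.concat(pat_frames, ignore_index=True), out / "patterns_mean.tsv")
    _write_table(pd.DataFrame(val_rows), out / "validation_mean.tsv")
    return out
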