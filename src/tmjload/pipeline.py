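"""Sweep driver: baseline plus shortening runs, summaries, exports, manifest."""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

from . import __version__
from .analysis import LoadSummary, SweepResult, summarize_run
from .config import RunConfig, config_digest
from .dynamics import SimulationDiverged, SimulationResult, simulate_open_close
from .geometry import ShorteningSpec, build_geometry, shorten_ramus

__all__ = ["RunManifest", "run_single", "run_sweep", "write_outputs"]


@dataclass
class RunManifest:
    """Per-sweep bookkeeping: config digest, run status, file registry."""

    config_digest: str
    software_version: str
    runs: dict = field(default_factory=dict)      # label -> status string
    files: list = field(default_factory=list)     # registered output paths

    def register(self, path) -> None:
        self.files.append(str(path))

    def to_json_dict(self) -> dict:
        return {
            "config_digest": self.config_digest,
            "software_version": self.software_version,
            "runs": dict(self.runs),
            "files": sorted(self.files),
        }


def run_single(cfg: RunConfig, shortening_mm: float = 0.0,
               side: str | None = None, duration: float | None = None) -> SimulationResult:
    """One open-close simulation at the given shortening (0 = baseline)."""
    import dataclasses

    geom = build_geometry(cfg.geometry)
    if shortening_mm > 0:
        geom = shorten_ramus(geom, ShorteningSpec(side=side or cfg.shortening_side,
                                                  distance_mm=shortening_mm))
    # the compressed layer is the whole fossa-disc-condyle stack of this geometry
    contact = dataclasses.replace(cfg.contact, layer_thickness=cfg.geometry.stack_thickness)
    return simulate_open_close(
        geom, {"cartilage": cfg.cartilage, "disc": cfg.disc},
        protocol=cfg.protocol, dt=cfg.dt, contact_params=contact,
        dynamics_params=cfg.dynamics, duration=duration)


def run_sweep(cfg: RunConfig, outdir=None, write: bool = True,
              progress=None) -> tuple[SweepResult, RunManifest]:
    """Baseline then each shortening with identical settings.

    A diverged run is marked failed in the manifest and the sweep continues;
    failed runs are excluded from the summary table.  Outputs are rewritten
    deterministically, so identical configs give identical files.
    """
    outdir = pathlib.Path(outdir if outdir is not None else cfg.output_dir)
    manifest = RunManifest(config_digest=config_digest(cfg), software_version=__version__)
    results: dict[float, SimulationResult] = {}
    labels = [("baseline", 0.0)] + [(f"shortening_{s:g}mm", float(s))
                                    for s in cfg.shortenings_mm]
    for label, s in labels:
        try:
            if progress:
                progress(label)
            results[s] = run_single(cfg, s)
            manifest.runs[label] = "ok"
        except SimulationDiverged as exc:
            manifest.runs[label] = f"failed: {exc}"

    summaries: list[LoadSummary] = []
    baseline: LoadSummary | None = None
    for label, s in labels:
        if s not in results:
            continue
        res = results[s]
        summ = summarize_run(res.time_ms, res.mean_force, label=label, shortening_mm=s)
        if s == 0.0:
            baseline = summ
        else:
            summaries.append(summ)
    if baseline is None:
        raise SimulationDiverged("baseline run failed; no summary possible")
    sweep = SweepResult.from_summaries(baseline, summaries)

    if write:
        write_outputs(cfg, sweep, results, manifest, outdir)
    return sweep, manifest


def write_outputs(cfg: RunConfig, sweep: SweepResult, results, manifest: RunManifest,
                  outdir: pathlib.Path) -> None:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    table_path = outdir / "load_table.csv"
    sweep.table.to_csv(table_path, index=False)
    manifest.register(table_path)

    summary_path = outdir / "sweep_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(sweep.to_json_dict(), fh, indent=2, sort_keys=True)
    manifest.register(summary_path)

    if cfg.write_traces:
        for s, res in results.items():
            p = outdir / f"traces_{s:g}mm.csv"
            res.to_dataframe().to_csv(p, index=False, float_format="%.6g")
            manifest.register(p)

    if cfg.write_stress_vtk:
        from .geometry import build_geometry
        from .vtkio import write_vtk_surface

        geom = build_geometry(cfg.geometry)
        for s, res in results.items():
            for t_key, fields in res.stress_fields.items():
                for name, values in fields.items():
                    side, patch = name.split("_", 1)
                    surf = geom.surfaces[side][patch]
                    p = outdir / f"stress_{s:g}mm_{t_key}ms_{name}.vtk"
                    write_vtk_surface(p, surf.vertices, surf.faces,
                                      {"von_mises_Pa": values})
                    manifest.register(p)

    if cfg.write_plots:
        _write_sweep_plots(sweep, outdir, manifest)

    config_path = outdir / "config_used.yaml"
    from .config import save_config

    save_config(cfg, config_path)
    manifest.register(config_path)

    manifest_path = outdir / "manifest.json"
    manifest.register(manifest_path)
    with open(manifest_path, "w") as fh:
        json.dump(manifest.to_json_dict(), fh, indent=2, sort_keys=True)


def _write_sweep_plots(sweep: SweepResult, outdir: pathlib.Path, manifest: RunManifest) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = sweep.shortenings
    for phase, title in (("closed", "mouth closed"), ("open", "mouth open")):
        fig, ax = plt.subplots(figsize=(6, 4))
        for side, color in (("right", "tab:blue"), ("left", "tab:orange")):
            y = [s.forces[(side, phase)] for s in sweep.summaries]
            ax.plot(x, y, "o-", color=color,
                    label=f"{side} ({'fractured' if side == 'right' else 'non-fractured'})")
        ax.set_xlabel("ramus shortening (mm)")
        ax.set_ylabel("window-mean TMJ contact force (N)")
        ax.set_title(f"Contact forces during {title}")
        ax.legend()
        fig.tight_layout()
        p = outdir / f"sweep_{phase}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        manifest.register(p)
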