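"""End-to-end orchestration: run plan, windowing, weights, observables,
distributions, free-energy surface, correlation report, and PCA.

The run plan mirrors the MD campaign of the CPR study: per-entry redox
state, NADP⁺ occupancy, initial structural state (closed/open), method
(cMD/aMD), per-run length in μs and run count.  Plan arithmetic uses
exact rational numbers so μs totals printed to one decimal carry no
float drift.

Analyses pool snapshots across runs *after* per-run windowing (the last
0.5 μs of each run, by default conventions of the study) and reweight
jointly; per-run correlations are also reported as a diagnostic since
the pooling choice is a genuine ambiguity.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import geometry, pca as pca_mod, reweighting
from .constants import DEFAULT_TEMPERATURE
from .exceptions import StageError, ValidationError
from .model_io import (
    ALLOXAZINE_RING_ATOMS,
    SelectionSpec,
    Trajectory,
    read_deltav_log,
    read_pdb,
    resolve_selection,
)

__all__ = [
    "RunPlanEntry",
    "RunPlan",
    "default_run_plan",
    "plan_total_length",
    "load_run_plan",
    "distances_table",
    "corr_from_files",
    "run_analysis",
]


# ---------------------------------------------------------------------------
# run plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunPlanEntry:
    """One row of the MD campaign plan."""

    redox_state: str  # "oxidized" | "reduced"
    nadp_bound: bool
    initial_state: str  # "closed" | "open"
    md_method: str  # "cMD" | "aMD"
    length_per_run: Fraction  # μs
    n_runs: int

    def __post_init__(self):
        object.__setattr__(self, "length_per_run", Fraction(self.length_per_run))
        if self.redox_state not in ("oxidized", "reduced"):
            raise ValidationError(f"unknown redox state '{self.redox_state}'")
        if self.initial_state not in ("closed", "open"):
            raise ValidationError(f"unknown initial state '{self.initial_state}'")
        if self.md_method not in ("cMD", "aMD"):
            raise ValidationError(f"unknown MD method '{self.md_method}'")
        if self.length_per_run <= 0 or self.n_runs < 1:
            raise ValidationError("length_per_run must be > 0 and n_runs >= 1")

    @property
    def total_length(self) -> Fraction:
        return self.length_per_run * self.n_runs


@dataclass(frozen=True)
class RunPlan:
    entries: tuple[RunPlanEntry, ...]

    @property
    def total_length(self) -> Fraction:
        return sum((e.total_length for e in self.entries), Fraction(0))


def default_run_plan() -> RunPlan:
    """The CPR MD campaign this package's defaults mirror (86.4 μs total):
    16×0.2 μs cMD + 16×1.0 μs aMD per redox state from the closed form,
    8×0.2 μs cMD + 8×0.4 μs aMD from the open form, and the same
    closed-form set repeated without bound NADP⁺."""
    f = Fraction
    entries = []
    for redox in ("oxidized", "reduced"):
        entries += [
            RunPlanEntry(redox, True, "closed", "cMD", f("0.2"), 16),
            RunPlanEntry(redox, True, "closed", "aMD", f("1.0"), 16),
            RunPlanEntry(redox, True, "open", "cMD", f("0.2"), 8),
            RunPlanEntry(redox, True, "open", "aMD", f("0.4"), 8),
            RunPlanEntry(redox, False, "closed", "cMD", f("0.2"), 16),
            RunPlanEntry(redox, False, "closed", "aMD", f("1.0"), 16),
        ]
    return RunPlan(tuple(entries))


def plan_total_length(
    plan: RunPlan,
    redox_state: Optional[str] = None,
    md_method: Optional[str] = None,
    initial_state: Optional[str] = None,
    nadp_bound: Optional[bool] = None,
) -> Fraction:
    """Total simulated length (μs) over entries passing the filters.

    An empty selection sums to 0.
    """
    total = Fraction(0)
    for e in plan.entries:
        if redox_state is not None and e.redox_state != redox_state:
            continue
        if md_method is not None and e.md_method != md_method:
            continue
        if initial_state is not None and e.initial_state != initial_state:
            continue
        if nadp_bound is not None and e.nadp_bound != nadp_bound:
            continue
        total += e.total_length
    return total


def load_run_plan(path) -> RunPlan:
    """Read a run plan from YAML (list of entry mappings under 'entries')."""
    data = yaml.safe_load(Path(path).read_text())
    entries = tuple(
        RunPlanEntry(
            redox_state=e["redox_state"],
            nadp_bound=bool(e["nadp_bound"]),
            initial_state=e["initial_state"],
            md_method=e["md_method"],
            length_per_run=Fraction(str(e["length_per_run"])),
            n_runs=int(e["n_runs"]),
        )
        for e in data["entries"]
    )
    return RunPlan(entries)


# ---------------------------------------------------------------------------
# selections from config
# ---------------------------------------------------------------------------

_DEFAULT_RINGS = {
    "fad_ring": {"residue_names": ["FAD"], "atom_names": list(ALLOXAZINE_RING_ATOMS)},
    "fmn_ring": {"residue_names": ["FMN"], "atom_names": list(ALLOXAZINE_RING_ATOMS)},
    "heme": {"residue_names": ["HEM"]},
}


def selections_from_config(cfg: dict) -> dict[str, SelectionSpec]:
    """Build named SelectionSpecs from the 'selections' config mapping.

    Domain residue ranges are mandatory configuration (they are not
    derivable from the structure); cofactor rings default to the
    15-atom alloxazine set and the heme to all HEM atoms.
    """
    sel_cfg = dict(cfg)
    out = {}
    for name in ("fad_domain", "fmn_domain"):
        if name not in sel_cfg:
            raise ValidationError(f"selection config must define '{name}' residue ranges")
    for name, defaults in _DEFAULT_RINGS.items():
        sel_cfg.setdefault(name, defaults)
    for name, d in sel_cfg.items():
        out[name] = SelectionSpec.from_dict(name, d)
    return out


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------

def distances_table(
    trajectory: Trajectory,
    selections: dict[str, SelectionSpec],
    complex_ref: Optional[geometry.ComplexReference] = None,
) -> pd.DataFrame:
    """Per-frame observables: d_fad_fmn (interdomain COM distance),
    d_cofactor (alloxazine-ring COM distance), and — when a complex
    reference is supplied — the superposition-predicted d_fmn_heme."""
    top = trajectory.topology
    idx = {k: resolve_selection(top, s) for k, s in selections.items() if k != "heme"}
    rows = {
        "frame": np.arange(trajectory.n_frames),
        "time_ns": trajectory.times,
        "d_fad_fmn": np.empty(trajectory.n_frames),
        "d_cofactor": np.empty(trajectory.n_frames),
    }
    if complex_ref is not None:
        rows["d_fmn_heme"] = np.empty(trajectory.n_frames)
    for t in range(trajectory.n_frames):
        frame = trajectory.frame(t)
        rows["d_fad_fmn"][t] = geometry.interdomain_distance(
            frame, idx["fad_domain"], idx["fmn_domain"]
        )
        rows["d_cofactor"][t] = geometry.intercofactor_distance(
            frame, idx["fad_ring"], idx["fmn_ring"]
        )
        if complex_ref is not None:
            rows["d_fmn_heme"][t] = geometry.predict_fmn_heme_distance(
                frame, idx["fad_domain"], idx["fmn_ring"], complex_ref
            )
    return pd.DataFrame(rows)


def _read_distances_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header = line[1:].split()
                break
        else:
            raise ValidationError(f"{path}: distances TSV lacks a '#' header line")
    df.columns = header[: df.shape[1]]
    return df


def corr_from_files(
    distances_tsv,
    deltav_log=None,
    temperature: float = DEFAULT_TEMPERATURE,
    x_column: str = "d_fad_fmn",
    y_column: str = "d_fmn_heme",
) -> dict:
    """Correlation report from on-disk pipeline products.

    Reads the distances TSV (and optional ΔV log for snapshot weights;
    absent log = cMD conventions, uniform weights) and returns the
    weighted Pearson correlation with its effective sample size.
    """
    df = _read_distances_tsv(distances_tsv)
    for col in (x_column, y_column):
        if col not in df.columns:
            raise ValidationError(f"{distances_tsv}: missing column '{col}'")
    if deltav_log is not None:
        dv = read_deltav_log(deltav_log).to_numpy()
        if len(dv) != len(df):
            raise ValidationError("ΔV log length does not match distances table")
        weights = reweighting.snapshot_weights(dv, temperature)
    else:
        weights = np.full(len(df), 1.0 / len(df))
    r = reweighting.weighted_pearson(
        df[x_column].to_numpy(), df[y_column].to_numpy(), weights
    )
    return {
        "pearson_r": r,
        "n": int(len(df)),
        "ess": reweighting.effective_sample_size(weights),
        "x": x_column,
        "y": y_column,
        "temperature_K": temperature,
    }


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def _window_indices(times: np.ndarray, window_cfg: Optional[dict]) -> np.ndarray:
    if not window_cfg:
        return np.arange(len(times))
    if "last_fraction" in window_cfg:
        frac = float(window_cfg["last_fraction"])
        span = times[-1] - times[0]
        return reweighting.select_window(
            times, times[-1] - frac * span, np.nextafter(times[-1], np.inf)
        )
    return reweighting.select_window(
        times, float(window_cfg["t_start"]), float(window_cfg["t_end"])
    )


def run_analysis(config, out_dir, quiet: bool = True) -> dict:
    """Run the full analysis described by a declarative config.

    Config keys: ``trajectories`` (list of {pdb, deltav?}), ``selections``
    (domain/ring definitions), ``window`` ({last_fraction} or
    {t_start, t_end}, ns), ``temperature`` (K), ``bins``, optional
    ``complex_reference`` ({pdb}) and ``pca`` ({enabled, n_modes}).

    Products in ``out_dir``: distances.tsv, dist1d_*.tsv, fel.tsv,
    corr.json, PCA tables, and manifest.json capturing the full config
    and diagnostics.  Identical config + inputs give identical outputs.
    On failure the partial outputs are removed and a StageError names
    the failing stage.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    log: list[dict] = []

    def emit(path: Path):
        created.append(path)
        return path

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    for p in created:
                        p.unlink(missing_ok=True)
                    raise StageError(name, str(exc)) from exc
                log.append({"stage": name, "wall_s": round(time.perf_counter() - self.t0, 4)})
                if not quiet:
                    print(f"[{name}] {log[-1]['wall_s']:.2f}s")

        return _Ctx()

    temperature = float(cfg.get("temperature", DEFAULT_TEMPERATURE))
    n_bins = int(cfg.get("bins", 50))

    with stage("load"):
        sels = selections_from_config(cfg["selections"])
        runs = []
        input_hashes = {}
        for entry in cfg["trajectories"]:
            pdb_path = Path(entry["pdb"])
            if not pdb_path.exists():
                raise FileNotFoundError(f"trajectory file not found: {pdb_path}")
            traj = read_pdb(pdb_path)
            if not isinstance(traj, Trajectory):
                raise ValidationError(f"{pdb_path}: single-model PDB is not a trajectory")
            input_hashes[str(pdb_path)] = _sha256(pdb_path)
            if entry.get("deltav"):
                dv_path = Path(entry["deltav"])
                if not dv_path.exists():
                    raise FileNotFoundError(f"ΔV log not found: {dv_path}")
                dv = read_deltav_log(dv_path).to_numpy()
                if len(dv) != traj.n_frames:
                    raise ValidationError(
                        f"{dv_path}: {len(dv)} ΔV entries for {traj.n_frames} frames"
                    )
                traj = traj.with_delta_v(dv)
                input_hashes[str(dv_path)] = _sha256(dv_path)
            runs.append(traj)
        complex_ref = None
        if cfg.get("complex_reference"):
            ref_path = Path(cfg["complex_reference"]["pdb"])
            if not ref_path.exists():
                raise FileNotFoundError(f"complex reference not found: {ref_path}")
            ref_struct = read_pdb(ref_path)
            input_hashes[str(ref_path)] = _sha256(ref_path)
            complex_ref = geometry.ComplexReference(
                ref_struct, sels["fad_domain"], sels["fmn_ring"], sels["heme"]
            )

    with stage("window"):
        window_cfg = cfg.get("window")
        windowed = [run.subset(_window_indices(run.times, window_cfg)) for run in runs]
        run_sizes = [w.n_frames for w in windowed]
        pooled = Trajectory(
            windowed[0].topology,
            np.concatenate([w.coords for w in windowed]),
            # pooled pseudo-time: strictly increasing re-index (runs are
            # independent; only ordering matters downstream)
            np.arange(sum(run_sizes), dtype=float),
            np.concatenate(
                [
                    w.delta_v if w.delta_v is not None else np.zeros(w.n_frames)
                    for w in windowed
                ]
            ),
        )

    with stage("weights"):
        weights = reweighting.snapshot_weights(pooled.delta_v, temperature)
        ess = reweighting.effective_sample_size(weights)

    with stage("distances"):
        table = distances_table(pooled, sels, complex_ref)
        dist_path = emit(out / "distances.tsv")
        with open(dist_path, "w") as fh:
            fh.write("# " + "\t".join(table.columns) + "\n")
            table.to_csv(fh, sep="\t", header=False, index=False, float_format="%.8g")

    with stage("distributions"):
        dist_meta = {}
        for col in ("d_fad_fmn", "d_cofactor"):
            vals = table[col].to_numpy()
            edges = reweighting.default_edges(vals, weights, n_bins)
            mass, dropped = reweighting.weighted_histogram(vals, weights, edges)
            p = emit(out / f"dist1d_{col}.tsv")
            centers = 0.5 * (edges[:-1] + edges[1:])
            with open(p, "w") as fh:
                fh.write(f"# reweighted probability distribution of {col}\n")
                fh.write("# bin_center\tprobability_mass\n")
                for c, m in zip(centers, mass):
                    fh.write(f"{c:.6g}\t{m:.10g}\n")
            dist_meta[col] = {"n_dropped": dropped, "edges": [float(edges[0]), float(edges[-1])]}

    fel_meta = None
    if complex_ref is not None:
        with stage("fel"):
            x = table["d_fad_fmn"].to_numpy()
            y = table["d_fmn_heme"].to_numpy()
            xe = reweighting.default_edges(x, weights, n_bins)
            ye = reweighting.default_edges(y, weights, n_bins)
            fel = reweighting.free_energy_2d(x, y, weights, xe, ye, temperature)
            fel.write_tsv(emit(out / "fel.tsv"))
            fel_meta = {"bins": n_bins, "occupied_bins": int(np.count_nonzero(fel.occupied))}

    corr_report = None
    if complex_ref is not None:
        with stage("corr"):
            x = table["d_fad_fmn"].to_numpy()
            y = table["d_fmn_heme"].to_numpy()
            corr_report = {
                "pearson_r_pooled": reweighting.weighted_pearson(x, y, weights),
                "ess": ess,
                "n": int(len(x)),
                "per_run": [],
            }
            start = 0
            for size in run_sizes:
                sl = slice(start, start + size)
                if size >= 2:
                    corr_report["per_run"].append(
                        reweighting.weighted_pearson(
                            x[sl], y[sl], weights[sl] / weights[sl].sum()
                        )
                    )
                start += size
            p = emit(out / "corr.json")
            p.write_text(json.dumps(corr_report, indent=2))

    pca_meta = None
    pca_cfg = cfg.get("pca")
    if pca_cfg and pca_cfg.get("enabled", True):
        with stage("pca"):
            fit_spec = SelectionSpec("pca_fit", atom_names=frozenset({"CA"}))
            fit_idx = resolve_selection(pooled.topology, fit_spec)
            use_weights = None if pca_cfg.get("unweighted") else weights
            aligned, mean, n_iter = pca_mod.align_frames(
                pooled, fit_idx, frame_weights=use_weights
            )
            cov = pca_mod.covariance_matrix(aligned, fit_idx, use_weights)
            k = int(pca_cfg.get("n_modes", 3))
            modes = pca_mod.principal_modes(cov, k, mean[fit_idx])
            p = emit(out / "pca_eigenvalues.tsv")
            with open(p, "w") as fh:
                fh.write("# mode\teigenvalue_A2\n")
                for m in modes:
                    fh.write(f"{m.index}\t{m.eigenvalue:.10g}\n")
            for m in modes:
                mp = emit(out / f"pca_mode{m.index}.tsv")
                with open(mp, "w") as fh:
                    fh.write(f"# principal mode {m.index}, unit 3N vector components\n")
                    for v in m.vector:
                        fh.write(f"{v:.10g}\n")
                pca_mod.write_mode_arrows_pdb(
                    emit(out / f"pca_mode{m.index}_arrows.pdb"),
                    pooled, fit_idx, mean[fit_idx], m,
                )
            pca_meta = {
                "n_modes": k,
                "align_iterations": n_iter,
                "weighted": use_weights is not None,
                "eigenvalues_A2": [m.eigenvalue for m in modes],
            }

    with stage("manifest"):
        manifest = {
            "config": cfg,
            "temperature_K": temperature,
            "bins": n_bins,
            "window": cfg.get("window"),
            "com_convention": "mass-weighted over heavy atoms",
            "n_frames_pooled": int(pooled.n_frames),
            "frames_per_run": run_sizes,
            "effective_sample_size": ess,
            "distributions": dist_meta,
            "fel": fel_meta,
            "pca": pca_meta,
            "input_sha256": input_hashes,
            "stages": log,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    result = {"manifest": manifest, "distances": table}
    if corr_report is not None:
        result["corr"] = corr_report
    return result
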