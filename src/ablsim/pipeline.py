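"""End-to-end lesion experiments and quantitative analysis.

`run_case` executes one of the ten studied configurations on the
idealized shell: lesion construction, monodomain activation with the
atrial cell model, extraction of ablated/inactive-tissue fractions, then
a closed-loop circulation run in which the left-atrial chamber's
contractile elastance is scaled by the fraction of electrically active
tissue, its onset shifted by the activation delay, and its passive
elastance stiffened with the scar burden.  Biomarkers (SV, EF, dEF, AT,
IT, peak LA pressure, LV EDV/ESV) are collected per case.

The analysis layer reproduces the published-table statistics: ordinary
least-squares regressions of dEF against inactive- and ablated-tissue
fractions, the normalized sensitivity difference x_diff, and the
conduction-velocity-reduction experiment.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import circulation as circ
from . import lesions as les
from . import mesh as msh
from . import monodomain as md
from .cells import courtemanche as crn


@dataclass
class PipelineConfig:
    # geometry
    radius: float = 20.0
    wall_thickness: float = 4.5
    resolution: float = 6.0       # mechanics mesh; EP one refinement finer
    geometry_seed: int = 1
    # electrophysiology (conductivities tuned at the working resolution so
    # the control total atrial activation is ~100 ms)
    sigma_f: float = 1.1
    anisotropy: float = 2.0       # sigma_f / sigma_s
    ep_dt: float = 0.01           # ms
    ep_duration: float = 330.0    # ms, covers delayed appendage activation
    stim_sites: tuple = (("bachmann", 29.0), ("posterior_sup", 36.0),
                         ("posterior_mid", 42.0), ("coronary_sinus", 65.0))
    pacing_cycles: int = 2        # limit-cycle pre-pacing of the cell model
    lesion_width: float = 5.0     # mm
    # lumped mechanics coupling
    stiffening_gain: float = 0.6  # passive elastance rise per scar fraction
    scar_stiffness_scale: float = 1.0  # sensitivity knob (1 = reference 2mu/5alpha)
    circ_cycles: int = 25
    circ_dt: float = 2e-3         # s


@dataclass
class BiomarkerRow:
    case: str
    SV: float                 # mL
    EF: float                 # %
    dEF: float                # pp vs Control (filled by run_all)
    AT: float                 # %
    IT: float                 # %
    peak_LA_pressure: float   # mmHg
    LV_EDV: float             # mL
    LV_ESV: float             # mL
    total_activation_time: float  # ms
    mean_activation_time: float   # ms
    avpd: float = float("nan")    # mm, annulus-displacement analogue


def load_reference_table() -> pd.DataFrame:
    """The published per-case indicator table, bundled as a fixture."""
    with resources.files("ablsim.data").joinpath("lesion_indicators.csv").open() as fh:
        return pd.read_csv(fh)


def ef_from_volumes(times: np.ndarray, V: np.ndarray,
                    systole_window: float | None = None) -> tuple[float, float]:
    """Stroke volume and ejection fraction of an atrial volume trace.

    SV = V_max - V at peak atrial systole (the maximal blood output);
    EF = 100 SV / V_max.  `systole_window` limits the search for the
    emptying minimum to the start of the trace (seconds).
    """
    V = np.asarray(V, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(V) < 3:
        raise ValueError("volume trace too short")
    vmax = float(V.max())
    if systole_window is None:
        systole_window = times[0] + 0.4 * (times[-1] - times[0])
    sel = times <= systole_window
    vmin = float(V[sel].min())
    sv = vmax - vmin
    ef = 100.0 * sv / vmax if vmax > 0 else 0.0
    return sv, ef


def delta_ef(table: pd.DataFrame, case: str, ef_col: str = "EF_pct") -> float:
    """EF loss of `case` vs Control in percentage points."""
    if "Control" not in set(table["case"]):
        raise ValueError("control row missing")
    ef_control = float(table.loc[table["case"] == "Control", ef_col].iloc[0])
    ef_case = float(table.loc[table["case"] == case, ef_col].iloc[0])
    return ef_control - ef_case


def lesion_regression(x, y) -> tuple[float, float, float]:
    """OLS slope, intercept and R^2 of dEF against a tissue fraction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def reference_regressions(include_control: bool = False):
    """R^2 of dEF vs IT and vs AT over the printed table's ablation rows."""
    df = load_reference_table()
    if not include_control:
        df = df[df["case"] != "Control"]
    _, _, r2_it = lesion_regression(df["IT_pct"], df["dEF_pp"])
    _, _, r2_at = lesion_regression(df["AT_pct"], df["dEF_pp"])
    return r2_it, r2_at


# ---------------------------------------------------------------------------
# simulation pipeline


def _build_geometry(config: PipelineConfig):
    shell = msh.make_la_shell(config.radius, config.wall_thickness,
                              config.resolution, seed=config.geometry_seed)
    return shell


def _ep_initial_state(config: PipelineConfig, n: int) -> np.ndarray:
    from .cells.pacing import PacingProtocol, pace_to_limit_cycle

    if config.pacing_cycles <= 0:
        return crn.initial_state(n)
    proto = PacingProtocol(n_cycles=config.pacing_cycles)
    y, _ = pace_to_limit_cycle(proto, crn)
    return np.repeat(y[:, None], n, axis=1)


def run_ep(shell: msh.LabeledMesh, lesion: les.LesionSet,
           config: PipelineConfig, conductivity_scale: float = 1.0,
           _shared=None) -> md.EPSolution:
    ep = shell.ep
    sf = config.sigma_f * conductivity_scale
    cond = md.ConductivityField.from_mesh(
        ep, sf, sf / config.anisotropy, sf / config.anisotropy,
        scar_mask=lesion.ep_mask)
    stim = md.StimulusProtocol(sites=list(config.stim_sites), delta_rad=3.0)
    if _shared is not None and "y0" in _shared:
        y0 = _shared["y0"]
    else:
        y0 = _ep_initial_state(config, ep.n_vertices)
        if _shared is not None:
            _shared["y0"] = y0
    return md.solve_monodomain(ep, cond, stim, config.ep_duration,
                               model=crn, dt=config.ep_dt, initial_state=y0)


def run_case(case_name: str, config: PipelineConfig | None = None,
             seed: int = 0, out_dir: str | Path | None = None,
             _shared=None) -> BiomarkerRow:
    """One full lesion experiment; deterministic for a fixed seed.

    `_shared` optionally carries (shell, ep initial state) reused across
    cases of one sweep so the ten cases share identical geometry.
    """
    config = config or PipelineConfig()
    config = replace(config, geometry_seed=config.geometry_seed + seed)
    if _shared is None:
        shell = _build_geometry(config)
    else:
        shell = _shared["shell"]
    lesion = les.combine(shell, case_name, width=config.lesion_width)
    les.apply_to_mesh(shell, lesion)
    try:
        sol = run_ep(shell, lesion, config, _shared=_shared)
        at = les.ablated_fraction(shell, lesion)
        it = md.inactive_fraction(sol, shell.ep)
        ep = shell.ep
        vols = np.abs(ep.element_volumes())
        node_active = ~sol.inactive_mask
        elem_active = node_active[ep.tets].sum(axis=1) >= 3
        act_elem = elem_active & ~lesion.ep_mask
        with np.errstate(all="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                t_elem = np.nanmean(sol.activation[ep.tets], axis=1)
        mean_ta = float(np.nansum(t_elem[act_elem] * vols[act_elem])
                        / vols[act_elem].sum())
        total_ta = sol.total_activation_time
    finally:
        # restore region labels so a shared shell can be reused
        _clear_scar(shell)

    row = _biomarkers_from_ep(case_name, config, at, it, mean_ta, total_ta,
                              _shared)
    if out_dir is not None:
        _write_case_outputs(row, config, Path(out_dir))
    return row


def _clear_scar(shell: msh.LabeledMesh) -> None:
    shell.region[shell.region == msh.REGIONS["scar"]] = msh.REGIONS["LA"]
    if shell.ep is not None:
        shell.ep.region[shell.ep.region == msh.REGIONS["scar"]] = \
            msh.REGIONS["LA"]


def _biomarkers_from_ep(case_name: str, config: PipelineConfig, at: float,
                        it: float, mean_ta: float, total_ta: float,
                        _shared=None) -> BiomarkerRow:
    """Closed-loop run with the EP-informed left-atrial chamber."""
    params = circ.CircParams()
    la = params.chambers["LA"]
    control_mean_ta = (_shared or {}).get("control_mean_ta", mean_ta)
    stiff = 1.0 + config.stiffening_gain * (at / 100.0) \
        * config.scar_stiffness_scale
    params.chambers["LA"] = replace(
        la,
        active_fraction=max(0.0, 1.0 - it / 100.0),
        activation_delay=max(0.0, (mean_ta - control_mean_ta)) * 1e-3,
        passive_stiffening=stiff,
    )
    st, tr = circ.simulate(params, n_cycles=config.circ_cycles,
                           dt=config.circ_dt)
    n = int(round(params.cycle_length / config.circ_dt))
    t_cyc = tr["t"][-n:] - tr["t"][-n]
    v_la = tr["V_LA"][-n:]
    p_la = tr["p_LA"][-n:]
    v_lv = tr["V_LV"][-n:]
    sv, ef = ef_from_volumes(t_cyc, v_la)
    if _shared is not None:
        _shared.setdefault("control_mean_ta", mean_ta)
        _shared.setdefault("traces", {})[case_name] = tr
    return BiomarkerRow(
        case=case_name, SV=sv, EF=ef, dEF=float("nan"), AT=at, IT=it,
        peak_LA_pressure=float(p_la.max()), LV_EDV=float(v_lv.max()),
        LV_ESV=float(v_lv.min()), total_activation_time=total_ta,
        mean_activation_time=mean_ta)


def run_all(cases=les.CASES, config: PipelineConfig | None = None,
            seed: int = 0, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run the ten-case sweep on shared geometry; fills the dEF column."""
    config = config or PipelineConfig()
    shared = {"shell": _build_geometry(
        replace(config, geometry_seed=config.geometry_seed + seed))}
    rows = []
    ordered = ["Control"] + [c for c in cases if c != "Control"]
    for case in ordered:
        rows.append(run_case(case, config, seed=seed, _shared=shared))
    df = pd.DataFrame([asdict(r) for r in rows])
    ef_control = float(df.loc[df["case"] == "Control", "EF"].iloc[0])
    df["dEF"] = ef_control - df["EF"]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "biomarkers.csv", index=False, float_format="%.6f")
        (out / "run.json").write_text(json.dumps(
            {"config": asdict(config), "seed": seed,
             "config_hash": config_hash(config)}, indent=1, default=str))
    return df


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_case_outputs(row: BiomarkerRow, config: PipelineConfig,
                        out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([asdict(row)]).to_csv(out / "biomarkers.csv", index=False,
                                       float_format="%.6f")


# ---------------------------------------------------------------------------
# sensitivity and conduction-velocity experiments


@dataclass
class SensitivitySpec:
    """Scar-stiffness variants as (mu multiplier, alpha multiplier, isotropic)."""

    variants: tuple = ((1.0, 1.0, False), (1.0, 1.0, True), (2.0, 1.0, True),
                       (1.0, 5.0, True), (4.0, 10.0, True))
    reference: tuple = (2.0, 5.0, True)

    def __post_init__(self):
        for mu_m, a_m, _ in (*self.variants, self.reference):
            if mu_m <= 0 or a_m <= 0:
                raise ValueError("multipliers must be positive")


def x_diff(x: np.ndarray, x_ref: np.ndarray) -> np.ndarray:
    """Relative difference normalized by the reference peak-to-peak range."""
    x = np.asarray(x, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    ptp = x_ref.max() - x_ref.min()
    if ptp == 0:
        raise ValueError("constant reference trace")
    return (x - x_ref) / ptp


def _stiffness_scale(mu_mult: float, alpha_mult: float,
                     reference=(2.0, 5.0)) -> float:
    """Lumped scar-stiffness scale of a (mu, alpha) variant vs the reference."""
    return (mu_mult * alpha_mult) / (reference[0] * reference[1])


def sensitivity_sweep(spec: SensitivitySpec, case: str = "PVI+AL+BL",
                      config: PipelineConfig | None = None,
                      seed: int = 0) -> dict:
    """x_diff traces of LA pressure and volume for each scar-stiffness variant.

    The activation sequence does not depend on the scar's mechanical
    stiffness, so the EP stage runs once and only the lumped mechanics is
    re-evaluated per variant.
    """
    config = config or PipelineConfig()
    shared = {"shell": _build_geometry(
        replace(config, geometry_seed=config.geometry_seed + seed))}
    run_case("Control", config, seed=seed, _shared=shared)
    shell = shared["shell"]
    lesion = les.combine(shell, case, width=config.lesion_width)
    les.apply_to_mesh(shell, lesion)
    try:
        sol = run_ep(shell, lesion, config, _shared=shared)
        at = les.ablated_fraction(shell, lesion)
        it = md.inactive_fraction(sol, shell.ep)
        ep = shell.ep
        vols = np.abs(ep.element_volumes())
        elem_active = (~sol.inactive_mask)[ep.tets].sum(axis=1) >= 3
        act = elem_active & ~lesion.ep_mask
        with np.errstate(all="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                t_elem = np.nanmean(sol.activation[ep.tets], axis=1)
        mean_ta = float(np.nansum(t_elem[act] * vols[act]) / vols[act].sum())
    finally:
        _clear_scar(shell)

    def traces_for(scale):
        cfg = replace(config, scar_stiffness_scale=scale)
        _biomarkers_from_ep(case, cfg, at, it, mean_ta,
                            sol.total_activation_time, shared)
        tr = shared["traces"].pop(case)
        n = int(round(circ.CircParams().cycle_length / config.circ_dt))
        return tr["t"][-n:] - tr["t"][-n], tr["p_LA"][-n:], tr["V_LA"][-n:]

    t, p_ref, v_ref = traces_for(_stiffness_scale(*spec.reference[:2]))
    out = {"t": t, "reference": (p_ref, v_ref), "variants": {}}
    for mu_m, a_m, iso in spec.variants:
        _, p, v = traces_for(_stiffness_scale(mu_m, a_m))
        out["variants"][(mu_m, a_m, iso)] = {
            "p_diff": x_diff(p, p_ref), "v_diff": x_diff(v, v_ref)}
    return out


def cv_reduction_experiment(case: str, reductions=(0.25, 0.5),
                            config: PipelineConfig | None = None,
                            seed: int = 0, shell=None) -> dict:
    """Rerun the EP stage with atrial conductivity reduced by each fraction.

    Returns the shared baseline solution and, per reduction level, the
    delayed activation map, total activation time and mean activation
    delay over commonly activated nodes.
    """
    for r in reductions:
        if not 0 <= r < 1:
            raise ValueError("reduction must be in [0, 1)")
    config = config or PipelineConfig()
    if shell is None:
        shell = _build_geometry(replace(config,
                                        geometry_seed=config.geometry_seed + seed))
    lesion = les.combine(shell, case, width=config.lesion_width)
    les.apply_to_mesh(shell, lesion)
    try:
        base = run_ep(shell, lesion, config)
        out = {"case": case, "baseline": base,
               "baseline_total_activation": base.total_activation_time,
               "levels": {}}
        for r in reductions:
            red = run_ep(shell, lesion, config, conductivity_scale=1.0 - r)
            both = ~np.isnan(base.activation) & ~np.isnan(red.activation)
            delay = float(np.mean(red.activation[both] - base.activation[both]))
            out["levels"][r] = {
                "solution": red,
                "total_activation": red.total_activation_time,
                "mean_activation_delay": delay,
            }
    finally:
        _clear_scar(shell)
    return out
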