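"""Shared fixtures.

The heavyweight objects (the idealized shell, the ten-case sweep, the
tuned conduction velocities) are session-scoped so every test module can
assert against the same simulated dataset without re-running physics.
The sweep uses a 50 us EP step and no pre-pacing to keep the suite fast;
the activation topology and tissue fractions are unchanged versus the
production settings (10 us, paced initial states).
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest

from ablsim import lesions as les
from ablsim import mesh as msh
from ablsim import monodomain as md
from ablsim import pipeline as pl
from ablsim.cells import surrogate

warnings.filterwarnings("ignore", message="Mean of empty slice")

FAST_CONFIG = pl.PipelineConfig(ep_dt=0.05, pacing_cycles=0)


@pytest.fixture(scope="session")
def shell():
    return msh.make_la_shell(resolution=6.0, seed=1)


@pytest.fixture(scope="session")
def fine_shell():
    return msh.make_la_shell(resolution=3.0, seed=1)


@pytest.fixture(scope="session")
def cable():
    return msh.make_cable(20.0, 0.25)


@pytest.fixture(scope="session")
def sweep():
    """Ten-case sweep on shared geometry: returns (DataFrame, shared dict)."""
    shared = {"shell": msh.make_la_shell(
        FAST_CONFIG.radius, FAST_CONFIG.wall_thickness,
        FAST_CONFIG.resolution, seed=FAST_CONFIG.geometry_seed)}
    rows = []
    for case in ["Control"] + [c for c in les.CASES if c != "Control"]:
        rows.append(pl.run_case(case, FAST_CONFIG, seed=0, _shared=shared))
    import pandas as pd
    from dataclasses import asdict

    df = pd.DataFrame([asdict(r) for r in rows])
    ef_control = float(df.loc[df["case"] == "Control", "EF"].iloc[0])
    df["dEF"] = ef_control - df["EF"]
    return df, shared


@pytest.fixture(scope="session")
def al_activation(sweep):
    """Appendage activation with and without the anterior line."""
    _, shared = sweep
    sh = shared["shell"]
    out = {}
    for case in ("Control", "PVI+AL"):
        lesion = les.combine(sh, case, width=FAST_CONFIG.lesion_width)
        les.apply_to_mesh(sh, lesion)
        try:
            sol = pl.run_ep(sh, lesion, FAST_CONFIG, _shared=shared)
        finally:
            pl._clear_scar(sh)
        laa = sh.vertex_sets["appendage"]
        out[case] = float(np.nanmean(sol.activation[laa]))
    return out


@pytest.fixture(scope="session")
def tuned_cv():
    """Conductivities tuned to the stated fiber/sheet velocity targets."""
    sig_f, cv_f = md.tune_conductivity(0.6, axis="f", model=surrogate)
    cab_s = msh.make_cable(20.0, 0.25, axis="s")
    sig_s, cv_s = md.tune_conductivity(0.4, fixture=cab_s, axis="s",
                                       model=surrogate)
    return {"sigma_f": sig_f, "cv_f": cv_f, "sigma_s": sig_s, "cv_s": cv_s}
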