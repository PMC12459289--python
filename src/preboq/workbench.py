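"""Fixtures, model serialization, experiment orchestration, and the CLI.

Everything is expressed in atomic units internally; device parameters enter
in SI units and are converted once in :mod:`preboq.open_system`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from .cmqb_mapping import assemble_cmqb, export_term_table, gate_count_report
from .observables import fidelity, fractional_occupation, nuclear_density
from .open_system import DeviceParameters, NoiseModel, lindblad_evolve
from .propagation import TrotterSchedule, exact_evolve, prepare_initial_state, trotter_evolve
from .resources import scaling_report
from .shin_metiu import ShinMetiuParameters, build_model
from .vibronic_hamiltonian import IntegralExpansion, ModeSet, build_hamiltonian


# ---------------------------------------------------------------------------
# fixture generation

def _random_hermitian(rng, shape) -> np.ndarray:
    a = rng.normal(size=shape)
    return 0.5 * (a + np.swapaxes(a, -1, -2))


def generate_fixture(profile: str, seed: int = 0, *, n_orbitals: int = 4,
                     n_modes: int = 1, coupling_scale: float = 0.05,
                     two_electron_scale: float = 0.1, omega: float = 1.0) -> dict:
    """Seed-deterministic model definitions for the supported profiles.

    ``random-vibronic`` draws Hermitian integral tensors with a controlled
    vibronic coupling scale (the order-1 tensors and d); ``two-level-toy`` is
    a single electron hopping between two orbitals, linearly coupled to one
    mode; ``shin-metiu`` defers to the grid pipeline defaults.
    """
    rng = np.random.default_rng(seed)
    if profile == "shin-metiu":
        return {"profile": "shin-metiu", "parameters": asdict(ShinMetiuParameters())}
    if profile == "two-level-toy":
        model = {
            "profile": "explicit",
            "n_orbitals": 2, "n_modes": 1, "order": 1,
            "modes": {"omegas": [omega], "q0": [0.0], "cutoffs": [8]},
            "h": {"0": [[0.5, coupling_scale], [coupling_scale, -0.5]],
                  "1": [[[0.0, coupling_scale], [coupling_scale, 0.0]]]},
            "vnn": {"0,0": 0.0},
        }
        return model
    if profile == "random-vibronic":
        no, nm = n_orbitals, n_modes
        h0 = _random_hermitian(rng, (no, no))
        h1 = coupling_scale * _random_hermitian(rng, (nm, no, no))
        d1 = rng.normal(size=(nm, no, no)) * coupling_scale
        d1 = 0.5 * (d1 - np.swapaxes(d1, -1, -2))
        v0 = two_electron_scale * rng.normal(size=(no,) * 4)
        v0 = 0.5 * (v0 + v0.transpose(2, 3, 0, 1))   # Hermiticity for real orbitals
        v0 = 0.5 * (v0 + v0.transpose(1, 0, 3, 2))   # particle exchange
        model = {
            "profile": "explicit",
            "n_orbitals": no, "n_modes": nm, "order": 1,
            "modes": {"omegas": [omega] * nm, "q0": [0.0] * nm, "cutoffs": [6] * nm},
            "h": {"0": h0.tolist(), "1": h1[None].reshape(nm, no, no).tolist()},
            "d": {"0": d1.tolist()},
            "v": {"0": v0.tolist()},
            "vnn": {},
        }
        return model
    raise ValueError(f"unknown fixture profile {profile!r}")


def expansion_from_model(model: dict) -> tuple[IntegralExpansion, ModeSet]:
    """Materialize an explicit model definition dict."""
    if model.get("profile") == "shin-metiu":
        raise ValueError("shin-metiu models are built by preboq.shin_metiu.build_model")
    no, nm, k = model["n_orbitals"], model["n_modes"], model["order"]
    expansion = IntegralExpansion(no, nm, k)
    for m_str, tensor in model.get("h", {}).items():
        expansion.h[int(m_str)] = np.asarray(tensor, dtype=complex)
    for m_str, tensor in model.get("d", {}).items():
        expansion.d[int(m_str)] = np.asarray(tensor, dtype=complex)
    for m_str, tensor in model.get("g", {}).items():
        expansion.g[int(m_str)] = np.asarray(tensor, dtype=complex)
    for m_str, tensor in model.get("v", {}).items():
        expansion.v[int(m_str)] = np.asarray(tensor, dtype=complex)
    for powers, coeff in model.get("vnn", {}).items():
        key = tuple(int(x) for x in str(powers).split(","))
        if coeff:
            expansion.vnn[key] = float(coeff)
    # re-coerce to complex arrays with the declared shapes
    expansion.__post_init__()
    modes = ModeSet(tuple(model["modes"]["omegas"]), tuple(model["modes"]["q0"]),
                    tuple(model["modes"]["cutoffs"]))
    return expansion, modes


def save_model(model: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model, fh, sort_keys=True)


def load_model(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def model_hash(model: dict) -> str:
    return hashlib.sha256(json.dumps(model, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# experiments

@dataclass
class ExperimentConfig:
    """A reproducible end-to-end run bound to one model definition."""

    model: dict
    dt: float = 0.1
    n_steps: int = 100
    exact: bool = True
    trotter: bool = True
    noise: bool = False
    device: dict = field(default_factory=dict)
    initial_onv: tuple = ()
    observables: tuple = ("fidelity", "fon")
    seed: int = 0
    output_dir: str = "preboq_out"

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> dict:
    """Build the model, evolve, and write fidelity / FON time series."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.model.get("profile") == "shin-metiu":
        params = ShinMetiuParameters(**config.model.get("parameters", {}))
        sm = build_model(params)
        ham, psi0, layout = sm.hamiltonian, sm.initial_state, sm.layout
    else:
        expansion, modes = expansion_from_model(config.model)
        sq = build_hamiltonian(expansion, modes)
        ham = assemble_cmqb(sq)
        layout = modes.layout(ham.n_qubits)
        onv = config.initial_onv or tuple([1] * 0 + [0] * layout.n_qubits)
        psi0 = prepare_initial_state(onv, layout, modes)

    schedule = TrotterSchedule(config.dt, config.n_steps)
    times = np.linspace(0.0, schedule.total_time, config.n_steps + 1)
    results: dict = {"config_hash": config.digest(), "model_hash": model_hash(config.model),
                     "gates": gate_count_report(ham)}
    frames = {}
    if config.exact:
        exact = exact_evolve(ham, psi0, times)
        frames["exact"] = exact
    if config.trotter:
        trot = trotter_evolve(ham, psi0, schedule)
        frames["trotter"] = trot
    rows = []
    for i, t in enumerate(times):
        row = {"time": t}
        for name, traj in frames.items():
            for p in range(layout.n_qubits):
                row[f"fon{p + 1}_{name}"] = fractional_occupation(traj.states[i], layout, p)
        if "exact" in frames and "trotter" in frames:
            row["fidelity_trotter"] = fidelity(frames["trotter"].states[i],
                                               frames["exact"].states[i])
        rows.append(row)
    df = pd.DataFrame(rows)
    csv_path = outdir / f"experiment_{results['config_hash']}.csv"
    df.to_csv(csv_path, index=False)
    results["timeseries_csv"] = str(csv_path)

    if config.noise:
        device = DeviceParameters(**config.device)
        noise = NoiseModel.from_device(ham, device, config.dt)
        rho0 = np.outer(psi0.amplitudes, psi0.amplitudes.conj())
        noisy = lindblad_evolve(ham, rho0, noise, times, layout,
                                trotterized=True, schedule=schedule)
        fons = [fractional_occupation(s, layout, 0) for s in noisy.states]
        pd.DataFrame({"time": noisy.times, "fon1_noisy": fons}).to_csv(
            outdir / f"noise_{results['config_hash']}.csv", index=False)
        results["noise_rates"] = {"jumps": [(j.kind, j.index, j.rate) for j in noise.jumps]}
    report_path = outdir / f"report_{results['config_hash']}.json"
    with open(report_path, "w") as fh:
        json.dump(results, fh, indent=2, default=str)
    results["report_json"] = str(report_path)
    return results


# ---------------------------------------------------------------------------
# CLI

@click.group()
def cli():
    """Pre-Born-Oppenheimer qubit-boson dynamics emulator."""


@cli.command()
@click.option("--profile", default="shin-metiu",
              type=click.Choice(["shin-metiu", "random-vibronic", "two-level-toy"]))
@click.option("--seed", default=0, type=int)
@click.option("-o", "--output", default="model.yaml", type=click.Path())
def fixture(profile, seed, output):
    """Generate a model-definition file."""
    save_model(generate_fixture(profile, seed), output)
    click.echo(f"wrote {output}")


@cli.command("build-model")
@click.option("--profile", default="shin-metiu")
@click.option("-o", "--output", default="model_terms.csv", type=click.Path())
def build_model_cmd(profile, output):
    """Build the Shin-Metiu model and export its qubit-boson term table."""
    if profile != "shin-metiu":
        raise click.UsageError("only the shin-metiu profile builds a grid model")
    sm = build_model()
    export_term_table(sm.hamiltonian, output, Path(output).with_suffix(".json"))
    click.echo(f"{sm.hamiltonian.n_op} terms on {sm.hamiltonian.n_qubits} qubits -> {output}")


@cli.command()
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--dt", default=5.6, type=float)
@click.option("--steps", default=10, type=int)
@click.option("--noise/--no-noise", default=False)
@click.option("--outdir", default="preboq_out", type=click.Path())
def evolve(model_path, dt, steps, noise, outdir):
    """Exact + Trotter (optionally noisy) evolution of a model file."""
    config = ExperimentConfig(load_model(model_path), dt=dt, n_steps=steps,
                              noise=noise, output_dir=outdir)
    results = run_experiment(config)
    click.echo(json.dumps({k: v for k, v in results.items() if isinstance(v, str)}, indent=2))


@cli.command()
@click.option("--xi", default=1.26, type=float, help="momentum grid spacing (a.u.)")
@click.option("--npoints", default=250, type=int)
@click.option("--time", "t_end", default=56.1, type=float)
@click.option("-o", "--output", default="nuclear_density.csv", type=click.Path())
def tomography(xi, npoints, t_end, output):
    """Nuclear density of the charge-transfer model by characteristic tomography."""
    sm = build_model()
    traj = exact_evolve(sm.hamiltonian, sm.initial_state, [t_end])
    # --xi is conjugate to the unweighted ion coordinate R; tomography runs in
    # the mass-weighted coordinate internally
    sqrt_m = np.sqrt(sm.params.mass)
    grid = nuclear_density(traj.final(), sm.layout, sm.modes,
                           xi_spacing=xi / sqrt_m, n_points=npoints,
                           coordinate="R", mass=sm.params.mass)
    pd.DataFrame({"R": grid.axes["R"], "density": grid.values}).to_csv(output, index=False)
    click.echo(f"resolution {grid.resolution / sqrt_m:.4f} a.u. in R -> {output}")


@cli.command()
@click.option("--nbo", default=2, type=int, help="number of retained BO states")
@click.option("--exclude-ground/--include-ground", default=True)
@click.option("--time", "t_end", default=56.1, type=float)
@click.option("-o", "--output", default="bo_run.csv", type=click.Path())
def bo(nbo, exclude_ground, t_end, output):
    """Born-Huang / GBOA propagation of the charge-transfer model."""
    from .bo_reference import born_huang_propagate, born_huang_setup

    sm = build_model()
    setup = born_huang_setup(sm.expansion, sm.modes, sm.layout,
                             include_g=sm.params.include_g)
    n_states = setup.sector.shape[1]
    start = 1 if (exclude_ground and nbo < n_states) else 0
    states = list(range(start, start + nbo))
    times = np.linspace(0.0, t_end, 21)
    traj = born_huang_propagate(setup, sm.initial_state, times, bo_states=states)
    exact = exact_evolve(sm.hamiltonian, sm.initial_state, times)
    rows = [{"time": t,
             "fon1_bo": fractional_occupation(s, sm.layout, 0),
             "fon1_exact": fractional_occupation(e, sm.layout, 0),
             "fidelity_vs_exact": fidelity(s, e)}
            for t, s, e in zip(times, traj.states, exact.states)]
    pd.DataFrame(rows).to_csv(output, index=False)
    click.echo(f"BO states {states} of {n_states}; "
               f"truncation loss {traj.metadata['truncation_loss']:.3f} -> {output}")


@cli.command()
@click.option("--no-range", "no_range", default="4:33:2")
@click.option("--ne-ratio", default=6.0, type=float)
@click.option("--spin", default=0.0, type=float)
@click.option("-o", "--output", default="scaling.csv", type=click.Path())
def resources(no_range, ne_ratio, spin, output):
    """CSF-count and qubit-count scaling table."""
    start, stop, step = (int(x) for x in no_range.split(":"))
    df = scaling_report(range(start, stop, step), ratio=ne_ratio, spin=spin)
    df.to_csv(output, index=False)
    click.echo(f"wrote {output} ({len(df)} rows)")


if __name__ == "__main__":
    cli()
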