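import numpy as np
import pytest

from tocky import (
    MeasurementModel,
    MixtureComponent,
    TimerKineticParams,
    TranscriptionProgram,
    derive_thresholds,
    gate_timer_positive,
    simulate_population,
    timer_transform,
)


@pytest.fixture
def params():
    return TimerKineticParams()


@pytest.fixture
def noise_free():
    return MeasurementModel.noise_free()


@pytest.fixture
def persistent_events(params, noise_free):
    """Noise-free homogeneous persistent-steady-state sample, transformed."""
    sample = simulate_population(
        [MixtureComponent(TranscriptionProgram.persistent(), 1.0, 2000.0)],
        n_cells=200,
        params=params,
        noise=noise_free,
        rate_cv=0.0,
        seed=7,
    )
    thresholds = derive_thresholds(sample.control)
    events = gate_timer_positive(sample.events, thresholds)
    return timer_transform(events)


def numerical_ode_trajectory(program, params, times):
    """Independent oracle: adaptive numerical integration of the cascade."""
    from scipy.integrate import solve_ivp

    a = params.translation_rate

    if params.include_mrna_stage:

        def rhs(t, x):
            s = program.rate_at(t)
            return [
                s - params.k_mrna * x[0],
                a * x[0] - params.k_blue * x[1],
                params.maturation_rate * x[1] - params.k_red * x[2],
            ]

        x0 = [0.0, 0.0, 0.0]
    else:

        def rhs(t, x):
            s = program.rate_at(t)
            return [
                s * a - params.k_blue * x[0],
                params.maturation_rate * x[0] - params.k_red * x[1],
            ]

        x0 = [0.0, 0.0]

    # integrate between rate breakpoints so the solver never steps across
    # a discontinuity of s(t)
    times = np.asarray(times, dtype=float)
    knots = np.unique(np.concatenate([[0.0], program.breakpoints(float(times[-1])), times]))
    x = np.array(x0)
    states = {knots[0]: x.copy()}
    for t0, t1 in zip(knots[:-1], knots[1:]):
        if t1 > t0:
            sol = solve_ivp(rhs, (t0, t1), x, rtol=1e-12, atol=1e-14, method="DOP853")
            assert sol.success
            x = sol.y[:, -1]
        states[t1] = x.copy()
    out = np.array([states[t] for t in times])
    if params.include_mrna_stage:
        return out[:, 1], out[:, 2]
    return out[:, 0], out[:, 1]


@pytest.fixture
def ode_oracle():
    return numerical_ode_trajectory
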