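"""Default numerical tolerances, collected in one place.

Every floating-point comparison in the package goes through an explicit
absolute + relative tolerance; these are the defaults, overridable per call.
"""

DEFAULTS = {
    # steady-state residual target for ODE integration (max-norm of dx/dt)
    "ode_steady_tol": 1e-10,
    # relative/absolute step tolerances handed to the stiff integrator
    "ode_rtol": 1e-10,
    "ode_atol": 1e-12,
    # base integration horizon is ode_horizon_factor / min(lambda); doubled on failure
    "ode_horizon_factor": 100.0,
    # maximum number of horizon doublings before declaring non-convergence
    "ode_max_doublings": 12,
    # fixed-point tolerance for |sigma(A(r*)) - r*|
    "fixed_point_tol": 1e-12,
    # back-substitution residual threshold for a rate accepted as the steady rate
    "back_substitution_tol": 1e-8,
    # generic relative tolerance for cross-checks (ODE vs spectral)
    "cross_check_rtol": 1e-6,
}
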