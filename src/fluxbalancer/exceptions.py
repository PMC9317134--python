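"""Exception hierarchy."""


class FluxBalancerError(Exception):
    """Base class for all package errors."""


class ModelError(FluxBalancerError):
    """Invalid or unparseable metabolic model."""


class ScenarioError(FluxBalancerError):
    """Invalid flux scenario (unknown reaction, bad variance, ...)."""


class InfeasibleBaseError(FluxBalancerError):
    """The base system (steady state + bounds + general constraints) is
    infeasible even before any rates are fixed; fixed-rate balancing cannot
    help.  Use generalized slack balancing on the offending constraint
    classes instead."""


class InfeasibleScenarioError(FluxBalancerError):
    """The scenario is infeasible; balance it before FBA/FVA."""


class BalancingError(FluxBalancerError):
    """Balancing cannot produce a feasible system with the selected slack
    targets (e.g. the inconsistency lives in a constraint class that was not
    selected for correction)."""


class SolverError(FluxBalancerError):
    """An optimization solver failed for reasons other than model
    infeasibility."""
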