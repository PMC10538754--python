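"""Exception hierarchy for cbfba."""


class CbfbaError(Exception):
    """Base class for all cbfba errors."""


class InfeasibleScenarioError(CbfbaError):
    """The flux space defined by model + scenario bounds contains no steady state.

    Carries the set of forced constraints (reactions with lower bound > 0 or
    upper bound < 0) that most often cause the conflict.
    """

    def __init__(self, message, forced_constraints=None):
        super().__init__(message)
        self.forced_constraints = forced_constraints or []


class InfeasibleProblemError(CbfbaError):
    """An LP/QP stage reported infeasibility."""


class SolverError(CbfbaError):
    """A solver failed for a reason other than infeasibility."""
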