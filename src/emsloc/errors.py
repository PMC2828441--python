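"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A generator or model parameter is outside its valid range."""


class CalibrationError(RuntimeError):
    """Noise calibration is impossible (e.g. zero predictor variance)."""


class GeometryError(ValueError):
    """A polygon or point configuration is degenerate."""


class StateError(RuntimeError):
    """An operation was called before its required inputs were computed."""


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"design matrix is rank deficient; collinear columns: {self.columns}"
        )


class StepwiseCyclingError(RuntimeError):
    """Stepwise selection revisited a predictor set (p_enter > p_remove?)."""


class DisconnectedNetworkError(RuntimeError):
    """Origin/destination pairs are not connected on the road graph."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(
            f"{len(self.pairs)} origin-destination pairs are unreachable; "
            f"first few: {self.pairs[:5]}"
        )
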