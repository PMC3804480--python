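"""Exception hierarchy.

Every error carries a short machine-greppable ``error_class`` used by the
command-line layer for single-line diagnostics.
"""


class KtapError(Exception):
    """Base class for all library errors."""

    error_class = "ktap-error"


class InvalidGridError(KtapError):
    error_class = "invalid-grid"


class ParameterError(KtapError):
    error_class = "parameter-error"


class DimensionError(KtapError):
    error_class = "dimension-error"


class CatalogueError(KtapError):
    error_class = "catalogue-error"


class NumericalError(KtapError):
    error_class = "numerical-error"


class ConfigurationError(KtapError):
    error_class = "configuration-error"


class ConfigError(KtapError):
    """Config-file validation failure; ``path`` names the offending key."""

    error_class = "config-error"

    def __init__(self, kind: str, path: str, detail: str = ""):
        self.kind = kind
        self.path = path
        msg = f"{kind}: {path}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
        self.error_class = f"config-{kind}"


class UnsupportedRegimeError(KtapError):
    error_class = "unsupported-regime"


class SingularityError(KtapError):
    error_class = "singularity"

    def __init__(self, singular_time: float, msg: str | None = None):
        self.singular_time = singular_time
        super().__init__(
            msg or f"Riccati trajectory singular at t = {singular_time:.6g}"
        )


class MissingDependencyError(KtapError):
    error_class = "missing-dependency"


class IntegratorError(KtapError):
    error_class = "integrator-failure"

    def __init__(self, breakdown_time: float, msg: str | None = None):
        self.breakdown_time = breakdown_time
        super().__init__(
            msg or f"ODE integrator broke down at t = {breakdown_time:.6g}"
        )
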