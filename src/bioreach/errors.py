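"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`BioreachError`,
so callers (and the CLI) can distinguish bad inputs from genuine bugs.
"""

from __future__ import annotations


class BioreachError(Exception):
    """Base class for all errors raised by bioreach."""


class UnitError(BioreachError, ValueError):
    """Incompatible or unknown measurement units (e.g. bundles vs kg)."""


class ConfigurationError(BioreachError, ValueError):
    """A parameter set that is structurally valid but arithmetically unusable,
    e.g. deduction fractions summing to >= 1, or zero total seed produced."""


class ConfigValidationError(BioreachError, ValueError):
    """Schema validation failure; carries *all* violations, not just the first."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "configuration failed validation with {} violation(s):\n  - {}".format(
                len(self.violations), "\n  - ".join(self.violations)
            )
        )
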