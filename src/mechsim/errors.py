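"""Exception hierarchy for mechsim."""

from __future__ import annotations


class MechsimError(Exception):
    """Base class for all mechsim errors."""


class MechanismParseError(MechsimError):
    """A mechanism document could not be parsed (malformed JSON/XML)."""


class MechanismValidationError(MechsimError):
    """A mechanism violates the domain-model invariants.

    Carries the full list of violation descriptions so callers can report
    every problem at once instead of failing on the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "mechanism validation failed:\n" + "\n".join(f"  - {v}" for v in violations)
        )


class SmartsParseError(MechsimError):
    """A SMARTS string falls outside the emitted dialect."""


class MrvParseError(MechsimError):
    """An MRV document is outside the supported subset."""


class GeneratorError(MechsimError):
    """A generator configuration is infeasible."""
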