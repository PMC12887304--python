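"""Exception types raised across the package."""


class AlchemnetError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(AlchemnetError):
    """A structure file could not be parsed under the named format."""


class StructureValidationError(AlchemnetError):
    """A parsed structure is chemically invalid (e.g. impossible valence)."""


class EmptyPocketError(AlchemnetError):
    """No protein atom lies within the pocket cutoff of any ligand atom."""


class InfeasibleScheduleError(AlchemnetError):
    """A single grid step already exceeds the adjacent-window threshold."""

    def __init__(self, lam_lo: float, lam_hi: float, gap: float, threshold: float):
        self.lam_lo, self.lam_hi, self.gap, self.threshold = lam_lo, lam_hi, gap, threshold
        super().__init__(
            f"grid interval [{lam_lo:.4f}, {lam_hi:.4f}] has free-energy gap "
            f"{gap:.3f} kcal/mol > threshold {threshold:.3f} kcal/mol; "
            "no schedule on this grid can satisfy the constraint"
        )


class ConfigError(AlchemnetError):
    """Invalid or unknown configuration keys/values."""
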