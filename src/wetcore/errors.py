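"""Exception hierarchy for wetcore."""


class WetcoreError(Exception):
    """Base class for all wetcore errors."""


class PDBParseError(WetcoreError):
    """A coordinate file could not be parsed; the message names the offending line."""


class EmptyModelError(WetcoreError):
    """The requested model contains no atoms."""


class RadiusAssignmentError(WetcoreError):
    """An element/atom class has no radius in the chosen table and no default exists."""


class ChainNotFoundError(WetcoreError):
    """A requested chain identifier is absent from the structure."""


class EmptyExposedSetError(WetcoreError):
    """No atom exceeds the exposure threshold, so burial levels are undefined."""


class UndefinedStatisticError(WetcoreError):
    """A descriptor is mathematically undefined for the given input (e.g. gini of all-zero counts)."""


class SuperpositionError(WetcoreError):
    """Rigid superposition could not be performed (too few pairs, length mismatch...)."""


class BFactorNormalizationError(WetcoreError):
    """The B-factor reference set is invalid (too small, zero spread, missing C-gamma)."""


class RegionConfigError(WetcoreError):
    """The region partition does not cover the interface or references unknown residues."""


class SyntheticSpecError(WetcoreError):
    """A synthetic-structure specification is inconsistent (clashes, unknown ids...)."""


class DataUnavailableError(WetcoreError):
    """A required accession coordinate file is neither bundled, on disk, nor downloadable."""
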