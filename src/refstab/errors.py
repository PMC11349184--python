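"""Exception hierarchy for refstab."""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class FormatError(RefstabError, ValueError):
    """An input file could not be parsed or lacks required columns."""


class DataIntegrityError(RefstabError, ValueError):
    """Input data violates an integrity constraint (duplicates, non-finite values)."""


class DimensionError(RefstabError, ValueError):
    """Too few genes or samples for the requested analysis."""


class GroupingError(RefstabError, ValueError):
    """A grouped analysis was requested with an unusable group structure."""
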