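"""Exception hierarchy. All package errors derive from ZoomsError so the
CLI can map data problems onto a single exit code."""


class ZoomsError(Exception):
    """Base class for all zoomsid errors."""


class PanelError(ZoomsError):
    """Malformed or inconsistent marker-panel file."""


class TaxonomyError(ZoomsError):
    """Malformed taxonomy file, or a name that does not resolve."""


class SpectrumError(ZoomsError):
    """Invalid spectrum or peak-list input."""


class ConfigError(ZoomsError):
    """Invalid pipeline or simulation configuration."""
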