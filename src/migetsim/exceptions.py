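"""Exception hierarchy.

Configuration problems (bad panels, circuits, designs, configs) and data
problems (unusable measurement input) are kept distinct so that the CLI can
map them to stable exit codes.
"""


class MigetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MigetError):
    """Invalid panel, circuit, grid, design or run configuration."""


class DataError(MigetError):
    """Measurement input that cannot be analysed (empty, degenerate, malformed)."""
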