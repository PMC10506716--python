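"""Exception taxonomy shared across the package.

``UsageError`` marks a caller mistake (bad parameter, absent node);
``GraphFormatError`` marks malformed input data.  The CLI maps them to
exit codes 2 and 1 respectively.
"""


class NetattackError(Exception):
    """Base class for all package-specific errors."""


class UsageError(NetattackError, ValueError):
    """Invalid call: out-of-range parameter, absent node, etc."""


class GraphFormatError(NetattackError, ValueError):
    """Malformed graph input (Matrix Market or edge-list file)."""
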