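"""Exception hierarchy.

All user-facing failures derive from :class:`PhyloringError` so the CLI can
map them onto exit codes (parse problems -> 2, anything unexpected -> 3).
"""


class PhyloringError(Exception):
    """Base class for all errors raised by phyloring."""


class FormatError(PhyloringError):
    """Input format could not be detected or is unsupported."""


class TreeParseError(PhyloringError):
    """A tree file failed to parse.

    Parameters
    ----------
    message:
        Human-readable description.
    offset:
        Character offset into the input where the problem was found
        (Newick), when known.
    line:
        1-based line number (plain-lineage format), when known.
    """

    def __init__(self, message, offset=None, line=None):
        loc = ""
        if offset is not None:
            loc = f" (at offset {offset})"
        elif line is not None:
            loc = f" (line {line})"
        super().__init__(message + loc)
        self.offset = offset
        self.line = line


class AnnotationError(PhyloringError):
    """An annotation file directive is malformed or untypeable."""

    def __init__(self, message, line=None):
        loc = f" (line {line})" if line is not None else ""
        super().__init__(message + loc)
        self.line = line


class LayoutError(PhyloringError):
    """The requested geometry cannot be computed (e.g. phylogram without
    branch lengths)."""


class ExportError(PhyloringError):
    """A profile / biomarker / BIOM input could not be converted."""
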