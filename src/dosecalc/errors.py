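"""Exception hierarchy shared across the dosimetry chain."""


class DosecalcError(Exception):
    """Base class for all package errors."""


class FormatError(DosecalcError):
    """A data file does not follow its declared dialect."""


class UnknownRegionError(DosecalcError):
    """A region name cannot be resolved against the canonical catalogue."""

    def __init__(self, name: str, candidates=()):
        self.name = name
        self.candidates = tuple(candidates)
        hint = f"; closest matches: {', '.join(self.candidates)}" if self.candidates else ""
        super().__init__(f"unknown region {name!r}{hint}")


class MissingGeometryError(DosecalcError):
    """No SAF entry exists for a requested (target, source, radiation type)."""

    def __init__(self, target: str, source: str, rtype: str | None = None):
        self.target = target
        self.source = source
        self.rtype = rtype
        what = f"(target={target!r}, source={source!r}"
        what += f", radiation_type={rtype!r})" if rtype else ")"
        super().__init__(f"no specific absorbed fraction available for {what}")


class DegenerateRemainderError(DosecalcError):
    """The accounted source masses exhaust (or exceed) the total-body mass."""
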