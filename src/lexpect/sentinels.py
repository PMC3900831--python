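"""Distinguished sentinel for estimates that cannot be calculated.

Sparse strata (e.g. no deaths observed at ages 85-89) yield rates and life
expectancies that are genuinely undefined.  They are carried through the
pipeline as the ``UNDEFINED`` singleton -- never as NaN or zero -- and are
rendered as an em dash in reports.
"""

from __future__ import annotations

UNDEFINED_DISPLAY = "—"  # em dash, the conventional "not calculable" mark


class _Undefined:
    """Singleton marking a non-calculable estimate."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False

    def __reduce__(self):
        return (_Undefined, ())


UNDEFINED = _Undefined()


def is_undefined(x) -> bool:
    """True if *x* is the undefined-estimate sentinel."""
    return x is UNDEFINED
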