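"""AAL-90 cortical/subcortical parcellation labels.

The 90-region automated anatomical labeling scheme (45 regions per
hemisphere, odd indices left, even indices right in the conventional
ordering) is the node definition used throughout diffusion connectome work.
Only the names are packaged here -- no atlas volume is shipped; registration
of the atlas to individual space is out of scope.
"""

from __future__ import annotations

__all__ = ["AAL90_ABBREVIATIONS", "aal90_labels"]

# Base abbreviations in AAL order; each expands to a left/right pair.
_AAL45 = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING",
    "SOG", "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG",
    "PCUN", "PCL", "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup",
    "MTG", "TPOmid", "ITG",
]

AAL90_ABBREVIATIONS: tuple[str, ...] = tuple(
    f"{name}.{side}" for name in _AAL45 for side in ("L", "R")
)


def aal90_labels() -> tuple[str, ...]:
    """The 90 AAL region abbreviations, e.g. ``PreCG.L``, ``HIP.R``."""
    return AAL90_ABBREVIATIONS
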