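"""Node labels for the 90-region AAL cortical/subcortical parcellation.

Regions are listed in standard AAL order, left/right interleaved, using the
conventional abbreviations with ``.L`` / ``.R`` suffixes (e.g. ``PreCG.L``,
``IFGoperc.L``).
"""

from __future__ import annotations

_AAL45 = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING", "SOG",
    "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG", "PCUN", "PCL",
    "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup", "MTG", "TPOmid",
    "ITG",
]

#: The 90 AAL node names in matrix order.
AAL90_NODES: list[str] = [f"{r}.{h}" for r in _AAL45 for h in ("L", "R")]


def default_node_names(n_nodes: int) -> list[str]:
    """AAL names when the network has 90 nodes, generic labels otherwise."""
    if n_nodes == 90:
        return list(AAL90_NODES)
    return [f"N{k:03d}" for k in range(n_nodes)]
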