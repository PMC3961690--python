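"""Bundled example data.

The in vivo DsbD activity measurements are published triplicate densitometry
readings (heme-stained cytochrome cd1 bands, arbitrary units) for full-length
wild-type DsbD and the Q488A and Q488K variants, collected on different days
(datasets 1-3 for Q488A, 1-2 for Q488K, each with its own wild-type control).
They serve as a complete worked input for :mod:`trxpka.activity`.
"""

from __future__ import annotations

from .activity import ReplicateSet

__all__ = ["dsbd_activity_replicates"]

# (variant construct, dataset label, variant readings, matched wild-type readings)
_DSBD_ACTIVITY = [
    ("Q488A-DsbD", "1", (15218.0, 16825.0, 15098.0), (17656.0, 22812.0, 20434.0)),
    ("Q488A-DsbD", "2", (14507.0, 15261.0, 16927.0), (19313.0, 20815.0, 19248.0)),
    ("Q488A-DsbD", "3", (13210.0, 15024.0, 14434.0), (19629.0, 17319.0, 19394.0)),
    ("Q488K-DsbD", "1", (25610.0, 26097.0, 25030.0), (25817.0, 26542.0, 22687.0)),
    ("Q488K-DsbD", "2", (22411.0, 22814.0, 22041.0), (18856.0, 18519.0, 17710.0)),
]


def dsbd_activity_replicates() -> dict[str, list[tuple[ReplicateSet, ReplicateSet]]]:
    """Return the DsbD activity replicate sets.

    Keys are the variant construct labels ("Q488A-DsbD", "Q488K-DsbD"); each
    value is a list of ``(variant, wild_type)`` :class:`ReplicateSet` pairs,
    one per dataset, with the wild-type control grown alongside the variant.
    """
    out: dict[str, list[tuple[ReplicateSet, ReplicateSet]]] = {}
    for construct, dataset, variant_readings, wt_readings in _DSBD_ACTIVITY:
        pair = (
            ReplicateSet(construct, dataset, variant_readings),
            ReplicateSet("Wild-type DsbD", dataset, wt_readings),
        )
        out.setdefault(construct, []).append(pair)
    return out
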