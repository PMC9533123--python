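"""Canonical 19-electrode 10-20 montage.

All result grids downstream (MSE profiles, PSD matrices, post-hoc t grids)
index electrodes in this fixed order, so electrode axes are comparable
across subjects, files and analyses.
"""

from __future__ import annotations

#: The 19 scalp sites of the international 10-20 system, in canonical order.
MONTAGE_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

N_ELECTRODES = len(MONTAGE_1020)

#: Frontal / parietal / temporal sites where the high-cognition group shows
#: elevated slow-scale entropy (13 sites; default effect set for simulation).
EFFECT_SITES_DEFAULT: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "P3", "P4", "F7", "T3", "T4", "T5", "T6", "Cz", "Pz",
)

_CANON = {lab.lower(): lab for lab in MONTAGE_1020}
# common clinical aliases for the mid-temporal / posterior-temporal sites
_CANON.update({"t7": "T3", "t8": "T4", "p7": "T5", "p8": "T6"})


def canonical_label(label: str) -> str | None:
    """Map a channel label to its canonical montage name, or None if unknown.

    Case-insensitive; strips common reference suffixes such as ``-A1A2`` or
    ``EEG `` prefixes, and accepts the modern T7/T8/P7/P8 aliases.
    """
    s = label.strip()
    if s.upper().startswith("EEG"):
        s = s[3:].lstrip(" :")
    for sep in ("-", " "):
        if sep in s:
            s = s.split(sep)[0]
    return _CANON.get(s.lower())


def montage_indices(labels: list[str]) -> dict[str, int]:
    """Map canonical label -> row index for a list of raw channel labels."""
    out: dict[str, int] = {}
    for i, lab in enumerate(labels):
        canon = canonical_label(lab)
        if canon is not None and canon not in out:
            out[canon] = i
    return out
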