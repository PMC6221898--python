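"""Electrode layouts for 10/20-system EEG caps.

The default layout is a 31-channel montage (32-electrode cap minus the
ground) with the five sagittal-midline sites and the two homologous
frontal pairs used for asymmetry analysis singled out.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ChannelLayout:
    """Named electrode montage with the channel groups the analysis needs.

    Parameters
    ----------
    names
        Ordered electrode labels; the row order of every recording.
    scalp
        Labels entering the across-electrode baseline average used for
        power normalization (N = ``len(scalp)``).
    midline
        Sagittal-midline sites (FZ, FCZ, CZ, CPZ, PZ by default).
    pairs
        Homologous (left, right) frontal pairs for asymmetry features.
    reference
        Optional mastoid labels for re-referencing.
    eog
        Optional electro-oculogram labels; never part of ``scalp``.
    """

    names: tuple[str, ...]
    scalp: frozenset[str]
    midline: frozenset[str]
    pairs: tuple[tuple[str, str], ...]
    reference: frozenset[str] = frozenset()
    eog: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("layout must name at least one electrode")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate electrode labels in layout")
        known = set(self.names)
        pair_members = {e for pair in self.pairs for e in pair}
        for group, label in [
            (self.scalp, "scalp"),
            (self.midline, "midline"),
            (pair_members, "pair"),
            (self.reference, "reference"),
            (self.eog, "eog"),
        ]:
            missing = set(group) - known
            if missing:
                raise ValueError(f"{label} labels not in layout: {sorted(missing)}")
        if self.midline & pair_members:
            raise ValueError("midline sites and asymmetry pair members must be disjoint")
        if self.scalp & (self.reference | self.eog):
            raise ValueError("scalp set must exclude reference and EOG labels")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """Row index of an electrode in the recording array."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"electrode {name!r} not in layout") from None

    def indices(self, names) -> list[int]:
        return [self.index(n) for n in names]


#: All 31 scalp sites of the default cap, in cap order.
SCALP_31 = (
    "FPZ", "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "FT7", "FC3", "FCZ", "FC4", "FT8", "T3", "C3", "CZ",
    "C4", "T4", "TP7", "CP3", "CPZ", "CP4", "TP8", "T5",
    "P3", "PZ", "P4", "T6", "O1", "OZ", "O2",
)

MIDLINE_SITES = ("FZ", "FCZ", "CZ", "CPZ", "PZ")

FRONTAL_PAIRS = (("FP1", "FP2"), ("F3", "F4"))

#: Electrodes feeding the whole-scalp band-power feature set: the 26-label
#: list minus PZ (a midline site), leaving 25 sites disjoint from the
#: midline features.
ORIGINAL75_ELECTRODES = (
    "FP1", "FP2", "F7", "F3", "F4", "F8", "FT7", "FC3", "FC4", "FT8",
    "T3", "C3", "C4", "T4", "TP7", "CP3", "CP4", "TP8", "T5", "P3",
    "P4", "T6", "O1", "OZ", "O2",
)

DEFAULT_LAYOUT = ChannelLayout(
    names=SCALP_31,
    scalp=frozenset(SCALP_31),
    midline=frozenset(MIDLINE_SITES),
    pairs=FRONTAL_PAIRS,
)


def small_layout(names: tuple[str, ...] = ("FP1", "FP2", "F3", "F4")) -> ChannelLayout:
    """Reduced layout for quick simulations; scalp set = all given names."""
    return ChannelLayout(
        names=names,
        scalp=frozenset(names),
        midline=frozenset(n for n in names if n in MIDLINE_SITES),
        pairs=tuple(p for p in FRONTAL_PAIRS if p[0] in names and p[1] in names),
    )
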