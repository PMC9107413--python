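"""Region atlas for 82-node gray-matter covariance networks.

The node set combines the 34 Desikan-Killiany cortical parcels per
hemisphere (mean thickness, mm) with 7 subcortical structures per
hemisphere (volume, mm^3): thalamus, caudate, putamen, pallidum,
hippocampus, amygdala and accumbens.

Region order is fixed and documented: left cortical (34), right cortical
(34), left subcortical (7), right subcortical (7).  All tabular and matrix
outputs across the package use this order.

Centroid coordinates are approximate MNI positions intended only for node
file export to BrainNet Viewer; they are not a stereotaxic reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CORTICAL = "cortical"
SUBCORTICAL = "subcortical"

LOBES = ("frontal", "temporal", "parietal", "occipital", "limbic", "subcortical")

# (name, lobe, |x|, y, z) — left hemisphere gets x = -|x|.
_DK_CORTICAL: list[tuple[str, str, float, float, float]] = [
    ("bankssts", "temporal", 54, -45, 10),
    ("caudalanteriorcingulate", "limbic", 5, 20, 30),
    ("caudalmiddlefrontal", "frontal", 36, 12, 48),
    ("cuneus", "occipital", 6, -80, 27),
    ("entorhinal", "temporal", 24, -8, -32),
    ("frontalpole", "frontal", 9, 60, -10),
    ("fusiform", "temporal", 36, -50, -18),
    ("inferiorparietal", "parietal", 43, -68, 35),
    ("inferiortemporal", "temporal", 50, -30, -26),
    ("insula", "limbic", 36, 0, 2),
    ("isthmuscingulate", "limbic", 7, -44, 25),
    ("lateraloccipital", "occipital", 32, -86, 5),
    ("lateralorbitofrontal", "frontal", 24, 30, -16),
    ("lingual", "occipital", 14, -66, -6),
    ("medialorbitofrontal", "frontal", 7, 34, -16),
    ("middletemporal", "temporal", 57, -28, -10),
    ("paracentral", "frontal", 8, -26, 58),
    ("parahippocampal", "temporal", 26, -32, -18),
    ("parsopercularis", "frontal", 48, 14, 14),
    ("parsorbitalis", "frontal", 44, 38, -10),
    ("parstriangularis", "frontal", 46, 30, 6),
    ("pericalcarine", "occipital", 10, -78, 8),
    ("postcentral", "parietal", 42, -24, 48),
    ("posteriorcingulate", "limbic", 6, -18, 38),
    ("precentral", "frontal", 38, -8, 48),
    ("precuneus", "parietal", 9, -58, 40),
    ("rostralanteriorcingulate", "limbic", 5, 34, 10),
    ("rostralmiddlefrontal", "frontal", 32, 44, 20),
    ("superiorfrontal", "frontal", 12, 28, 50),
    ("superiorparietal", "parietal", 24, -58, 56),
    ("superiortemporal", "temporal", 54, -18, 0),
    ("supramarginal", "parietal", 52, -42, 30),
    ("temporalpole", "temporal", 32, 12, -34),
    ("transversetemporal", "temporal", 44, -24, 10),
]

_SUBCORTICAL: list[tuple[str, float, float, float]] = [
    ("thalamus", 11, -18, 8),
    ("caudate", 13, 10, 10),
    ("putamen", 25, 0, 0),
    ("pallidum", 20, -4, 0),
    ("hippocampus", 26, -22, -14),
    ("amygdala", 24, -4, -18),
    ("accumbens", 9, 10, -8),
]


@dataclass(frozen=True)
class Region:
    """One network node: a cortical parcel or a subcortical structure."""

    name: str
    hemisphere: str  # "L" or "R"
    lobe: str
    tissue_class: str  # CORTICAL or SUBCORTICAL
    centroid: tuple[float, float, float]

    @property
    def measure(self) -> str:
        """Morphometric measure carried by this region."""
        return "thickness_mm" if self.tissue_class == CORTICAL else "volume_mm3"


@dataclass(frozen=True)
class AtlasDefinition:
    """Ordered collection of the 82 network regions."""

    regions: tuple[Region, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        n_cort = sum(r.tissue_class == CORTICAL for r in self.regions)
        n_sub = sum(r.tissue_class == SUBCORTICAL for r in self.regions)
        if (n_cort, n_sub) != (68, 14):
            raise ValueError(
                f"atlas must have 68 cortical + 14 subcortical regions, "
                f"got {n_cort} + {n_sub}"
            )
        for hemi, n_c, n_s in (("L", 34, 7), ("R", 34, 7)):
            got_c = sum(
                r.hemisphere == hemi and r.tissue_class == CORTICAL
                for r in self.regions
            )
            got_s = sum(
                r.hemisphere == hemi and r.tissue_class == SUBCORTICAL
                for r in self.regions
            )
            if (got_c, got_s) != (n_c, n_s):
                raise ValueError(f"hemisphere {hemi}: expected 34+7 regions")
        bad = {r.lobe for r in self.regions} - set(LOBES)
        if bad:
            raise ValueError(f"unknown lobe tags: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def index(self, name: str) -> int:
        for i, r in enumerate(self.regions):
            if r.name == name:
                return i
        raise KeyError(name)

    def mask(
        self,
        lobes: tuple[str, ...] | None = None,
        hemisphere: str | None = None,
        names: tuple[str, ...] | None = None,
    ) -> list[bool]:
        """Boolean selector over regions; conditions given are ANDed,
        except `names`, which is ORed in (a named region is always selected)."""
        out = []
        for r in self.regions:
            keep = True
            if lobes is not None and r.lobe not in lobes:
                keep = False
            if hemisphere is not None and r.hemisphere != hemisphere:
                keep = False
            if names is not None and r.name in names:
                keep = True
            out.append(keep)
        return out


def make_default_atlas() -> AtlasDefinition:
    """The packaged 82-region atlas (fixed order, see module docstring)."""
    regions: list[Region] = []
    for hemi, prefix, sign in (("L", "lh", -1.0), ("R", "rh", 1.0)):
        for name, lobe, x, y, z in _DK_CORTICAL:
            regions.append(
                Region(
                    name=f"{prefix}_{name}",
                    hemisphere=hemi,
                    lobe=lobe,
                    tissue_class=CORTICAL,
                    centroid=(sign * x, float(y), float(z)),
                )
            )
    # cortical blocks first (lh then rh), then subcortical blocks
    regions = regions[:34] + regions[34:]
    sub: list[Region] = []
    for hemi, prefix, sign in (("L", "lh", -1.0), ("R", "rh", 1.0)):
        for name, x, y, z in _SUBCORTICAL:
            sub.append(
                Region(
                    name=f"{prefix}_{name}",
                    hemisphere=hemi,
                    lobe="subcortical",
                    tissue_class=SUBCORTICAL,
                    centroid=(sign * x, float(y), float(z)),
                )
            )
    return AtlasDefinition(regions=tuple(regions + sub))
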