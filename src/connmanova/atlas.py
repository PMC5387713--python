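"""Parcel atlas: the ordered set of brain-region labels shared by all metric panels.

The default atlas has 165 parcels: 74 Destrieux-style cortical gyri/sulci per
hemisphere, 8 subcortical structures per hemisphere, plus the brain stem.
Labels carry an ``lh.`` / ``rh.`` / ``mid.`` hemisphere prefix, one label per
line in the on-disk format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import IntegrityError, SchemaError

_PREFIXES = ("lh.", "rh.", "mid.")

# Destrieux-style cortical parcellation, 74 gyri and sulci per hemisphere.
_CORTICAL = (
    "G_and_S_frontomargin",
    "G_and_S_occipital_inf",
    "G_and_S_paracentral",
    "G_and_S_subcentral",
    "G_and_S_transv_frontopol",
    "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant",
    "G_and_S_cingul-Mid-Post",
    "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral",
    "G_cuneus",
    "G_front_inf-Opercular",
    "G_front_inf-Orbital",
    "G_front_inf-Triangul",
    "G_front_middle",
    "G_front_sup",
    "G_Ins_lg_and_S_cent_ins",
    "G_insular_short",
    "G_occipital_middle",
    "G_occipital_sup",
    "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual",
    "G_oc-temp_med-Parahip",
    "G_orbital",
    "G_pariet_inf-Angular",
    "G_pariet_inf-Supramar",
    "G_parietal_sup",
    "G_postcentral",
    "G_precentral",
    "G_precuneus",
    "G_rectus",
    "G_subcallosal",
    "G_temp_sup-G_T_transv",
    "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar",
    "G_temp_sup-Plan_tempo",
    "G_temporal_inf",
    "G_temporal_middle",
    "Lat_Fis-ant-Horizont",
    "Lat_Fis-ant-Vertical",
    "Lat_Fis-post",
    "Pole_occipital",
    "Pole_temporal",
    "S_calcarine",
    "S_central",
    "S_cingul-Marginalis",
    "S_circular_insula_ant",
    "S_circular_insula_inf",
    "S_circular_insula_sup",
    "S_collat_transv_ant",
    "S_collat_transv_post",
    "S_front_inf",
    "S_front_middle",
    "S_front_sup",
    "S_interm_prim-Jensen",
    "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus",
    "S_oc_sup_and_transversal",
    "S_occipital_ant",
    "S_oc-temp_lat",
    "S_oc-temp_med_and_Lingual",
    "S_orbital_lateral",
    "S_orbital_med-olfact",
    "S_orbital-H_Shaped",
    "S_parieto_occipital",
    "S_pericallosal",
    "S_postcentral",
    "S_precentral-inf-part",
    "S_precentral-sup-part",
    "S_suborbital",
    "S_subparietal",
    "S_temporal_inf",
    "S_temporal_sup",
    "S_temporal_transverse",
)

_SUBCORTICAL = (
    "Thalamus-Proper",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens-area",
    "VentralDC",
)

assert len(_CORTICAL) == 74
assert len(_SUBCORTICAL) == 8


@dataclass(frozen=True)
class ParcelAtlas:
    """Ordered, unique parcel labels with a hemisphere prefix convention.

    The order is fixed and shared by every :class:`~connmanova.cohort.MetricPanel`
    built against the atlas.
    """

    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise SchemaError("atlas must contain at least one parcel label")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise IntegrityError(f"duplicate atlas labels: {dupes}")
        bad = [l for l in self.labels if not l.startswith(_PREFIXES)]
        if bad:
            raise SchemaError(
                f"atlas labels must start with one of {_PREFIXES}; offending: {bad[:5]}"
            )

    @property
    def p(self) -> int:
        """Number of parcels."""
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def hemisphere(self, label: str) -> str:
        """Return 'lh', 'rh' or 'midline' for a label of this atlas."""
        if label.startswith("lh."):
            return "lh"
        if label.startswith("rh."):
            return "rh"
        return "midline"

    def hemispheres(self) -> tuple[str, ...]:
        return tuple(self.hemisphere(l) for l in self.labels)


def default_atlas() -> ParcelAtlas:
    """The default whole-brain atlas with 165 parcels.

    Per hemisphere: 74 cortical gyri/sulci plus 8 subcortical structures;
    the brain stem is the single midline parcel (2*(74+8)+1 = 165).
    """
    labels = (
        tuple(f"lh.{l}" for l in _CORTICAL)
        + tuple(f"lh.{l}" for l in _SUBCORTICAL)
        + tuple(f"rh.{l}" for l in _CORTICAL)
        + tuple(f"rh.{l}" for l in _SUBCORTICAL)
        + ("mid.Brain-stem",)
    )
    return ParcelAtlas(labels)


# Table-2-style target regions: lateral temporal lobe, temporo-parieto-occipital
# junction and medial parietal lobe, both hemispheres (22 parcels).
_TARGET_BASE = (
    "G_pariet_inf-Angular",
    "S_parieto_occipital",
    "G_temporal_middle",
    "G_pariet_inf-Supramar",
    "G_cuneus",
    "G_temp_sup-Lateral",
    "S_interm_prim-Jensen",
    "S_temporal_sup",
    "G_insular_short",
    "G_precuneus",
    "G_temp_sup-Plan_polar",
)


def default_target_parcels() -> tuple[str, ...]:
    """The 22 default parcels carrying the plantable sex-by-diagnosis interaction."""
    return tuple(f"{h}.{l}" for h in ("lh", "rh") for l in _TARGET_BASE)


def synthetic_atlas(p: int) -> ParcelAtlas:
    """A placeholder atlas with ``p`` parcels for scaled-down simulations.

    Labels alternate between hemispheres (lh.P001, rh.P002, ...); if ``p`` is
    odd the last parcel is midline.
    """
    if p < 1:
        raise SchemaError("atlas size must be >= 1")
    labels = []
    for i in range(p):
        if i == p - 1 and p % 2 == 1:
            prefix = "mid"
        else:
            prefix = "lh" if i % 2 == 0 else "rh"
        labels.append(f"{prefix}.P{i + 1:03d}")
    return ParcelAtlas(tuple(labels))


def read_atlas(path) -> ParcelAtlas:
    """Read an atlas file: one prefixed label per line, order preserved."""
    with open(path, "rt", encoding="utf-8") as fh:
        labels = tuple(line.strip() for line in fh if line.strip())
    return ParcelAtlas(labels)


def write_atlas(atlas: ParcelAtlas, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for label in atlas.labels:
            fh.write(label + "\n")
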