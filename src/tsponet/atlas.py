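"""Region-of-interest atlas handling.

The similarity-network method is atlas-agnostic: any ordered list of brain
regions with hemisphere and tissue-class annotations works. The shipped
default is an 87-region parcellation in the FreeSurfer style (34
Desikan-Killiany cortical labels per hemisphere, 8 ASEG subcortical
structures per hemisphere, bilateral cerebellar cortex, and the brainstem),
ordered in hemisphere-by-class blocks: cortical left, cortical right,
subcortical left, subcortical right, cerebellar left/right, brainstem.
Homologous left/right regions are paired automatically from their names.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RoiAtlas", "load_atlas", "default_atlas", "reduced_atlas"]

TISSUE_CLASSES = ("cortical", "subcortical", "cerebellar", "brainstem")
HEMISPHERES = ("L", "R", "midline")

# block order used everywhere: class-major, left before right, midline last
_CLASS_ORDER = {"cortical": 0, "subcortical": 1, "cerebellar": 2, "brainstem": 3}
_HEMI_ORDER = {"L": 0, "R": 1, "midline": 2}

_DK_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]

_ASEG_SUBCORTICAL = [
    "Thalamus-Proper", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens-area", "VentralDC",
]


@dataclass(frozen=True)
class RoiAtlas:
    """Ordered region list with hemisphere/class annotations and homolog pairs.

    Attributes
    ----------
    roi_names : tuple of str
        Unique region labels in canonical block order.
    hemisphere : tuple of str
        One of ``L``, ``R``, ``midline`` per region.
    tissue_class : tuple of str
        One of ``cortical``, ``subcortical``, ``cerebellar``, ``brainstem``.
    homolog_map : dict
        Maps each lateralized region index to its contralateral partner index.
    """

    roi_names: tuple
    hemisphere: tuple
    tissue_class: tuple
    homolog_map: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.roi_names)
        if len(set(self.roi_names)) != n:
            dupes = sorted({x for x in self.roi_names if self.roi_names.count(x) > 1})
            raise ValueError(f"duplicate ROI names: {dupes}")
        if len(self.hemisphere) != n or len(self.tissue_class) != n:
            raise ValueError("hemisphere/tissue_class length mismatch")
        for h in self.hemisphere:
            if h not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere token {h!r}")
        for c in self.tissue_class:
            if c not in TISSUE_CLASSES:
                raise ValueError(f"unknown tissue class {c!r}")
        for i, j in self.homolog_map.items():
            if self.tissue_class[i] != self.tissue_class[j]:
                raise ValueError(
                    f"homolog pair ({self.roi_names[i]}, {self.roi_names[j]}) "
                    "crosses tissue classes"
                )
            if {self.hemisphere[i], self.hemisphere[j]} != {"L", "R"}:
                raise ValueError(
                    f"homolog pair ({self.roi_names[i]}, {self.roi_names[j]}) "
                    "is not a left/right pair"
                )

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)

    @property
    def n_edges(self) -> int:
        r = self.n_roi
        return r * (r - 1) // 2

    def homolog_pairs(self):
        """Unique (left_index, right_index) homolog pairs."""
        pairs = []
        for i, j in self.homolog_map.items():
            if self.hemisphere[i] == "L":
                pairs.append((i, j))
        return sorted(pairs)

    def index(self, name: str) -> int:
        return self.roi_names.index(name)


def _hemi_stem(name: str):
    """Return (hemisphere, lateral stem) inferred from a region label."""
    lowered = name.lower()
    for pre, hemi in (("ctx-lh-", "L"), ("ctx-rh-", "R"), ("left-", "L"),
                      ("right-", "R"), ("lh-", "L"), ("rh-", "R")):
        if lowered.startswith(pre):
            return hemi, name[len(pre):].lower()
    for suf, hemi in (("-l", "L"), ("-r", "R"), ("_l", "L"), ("_r", "R")):
        if lowered.endswith(suf):
            return hemi, lowered[: -len(suf)]
    return "midline", lowered


def _build(rows) -> RoiAtlas:
    """Assemble an atlas from (name, hemisphere, class) rows.

    Rows are reordered into the canonical class/hemisphere block order
    (stable within a block), then homologs are paired by lateral name stem.
    """
    for name, hemi, cls in rows:
        if cls not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {cls!r} for region {name!r}")
        if hemi not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere token {hemi!r} for region "
                             f"{name!r}")
    order = sorted(
        range(len(rows)),
        key=lambda i: (_CLASS_ORDER[rows[i][2]], _HEMI_ORDER[rows[i][1]], i),
    )
    rows = [rows[i] for i in order]
    names = tuple(r[0] for r in rows)
    hemis = tuple(r[1] for r in rows)
    classes = tuple(r[2] for r in rows)

    stems = {}
    homolog = {}
    for i, (name, hemi, cls) in enumerate(rows):
        if hemi == "midline":
            continue
        _, stem = _hemi_stem(name)
        key = (cls, stem)
        if key in stems:
            j = stems.pop(key)
            if hemis[j] == hemi:
                raise ValueError(f"regions {names[j]!r} and {name!r} share a "
                                 f"lateral stem but the same hemisphere")
            homolog[i] = j
            homolog[j] = i
        else:
            stems[key] = i
    if stems:
        unpaired = sorted(names[i] for i in stems.values())
        raise ValueError(f"unpaired lateralized regions (no contralateral "
                         f"homolog found): {unpaired}")
    return RoiAtlas(names, hemis, classes, homolog)


def default_atlas() -> RoiAtlas:
    """The full 87-region default atlas (68 cortical, 16 subcortical,
    2 cerebellar, 1 brainstem)."""
    rows = []
    for hemi, pre in (("L", "ctx-lh-"), ("R", "ctx-rh-")):
        rows += [(pre + lbl, hemi, "cortical") for lbl in _DK_CORTICAL]
    for hemi, pre in (("L", "Left-"), ("R", "Right-")):
        rows += [(pre + lbl, hemi, "subcortical") for lbl in _ASEG_SUBCORTICAL]
    rows += [("Left-Cerebellum-Cortex", "L", "cerebellar"),
             ("Right-Cerebellum-Cortex", "R", "cerebellar"),
             ("Brain-Stem", "midline", "brainstem")]
    return _build(rows)


def reduced_atlas() -> RoiAtlas:
    """A 20-region scaled-down atlas (10 homolog pairs) for fast simulation."""
    cortical = _DK_CORTICAL[:6]
    subcortical = _ASEG_SUBCORTICAL[:3]
    rows = []
    for hemi, pre in (("L", "ctx-lh-"), ("R", "ctx-rh-")):
        rows += [(pre + lbl, hemi, "cortical") for lbl in cortical]
    for hemi, pre in (("L", "Left-"), ("R", "Right-")):
        rows += [(pre + lbl, hemi, "subcortical") for lbl in subcortical]
    rows += [("Left-Cerebellum-Cortex", "L", "cerebellar"),
             ("Right-Cerebellum-Cortex", "R", "cerebellar")]
    return _build(rows)


def load_atlas(path_or_default="default") -> RoiAtlas:
    """Load an atlas from a CSV file with columns ``name,hemisphere,class``,
    or return a built-in one.

    Parameters
    ----------
    path_or_default : str or Path
        ``"default"`` for the 87-region atlas, ``"reduced"`` for the
        20-region test atlas, otherwise a path to a CSV file.
    """
    if path_or_default == "default":
        return default_atlas()
    if path_or_default == "reduced":
        return reduced_atlas()
    path = Path(path_or_default)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "hemisphere", "class"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"atlas file must have columns {sorted(required)}")
        for rec in reader:
            rows.append((rec["name"].strip(), rec["hemisphere"].strip(),
                         rec["class"].strip()))
    if not rows:
        raise ValueError(f"empty atlas file {path}")
    return _build(rows)
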