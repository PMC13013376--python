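"""Region labels for the 90-region AAL cortical/subcortical parcellation.

Labels follow the customary abbreviation scheme (odd indices left, even right
hemisphere in the standard ordering). Region numbering in every user-facing
interface is 1-based atlas order; ``AAL90_LABELS[i - 1]`` is region ``i``.
"""

from __future__ import annotations

_PAIRS = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri", "Frontal_Inf_Orb",
    "Rolandic_Oper", "Supp_Motor_Area", "Olfactory", "Frontal_Sup_Medial",
    "Frontal_Med_Orb", "Rectus", "Insula", "Cingulum_Ant", "Cingulum_Mid",
    "Cingulum_Post", "Hippocampus", "ParaHippocampal", "Amygdala", "Calcarine",
    "Cuneus", "Lingual", "Occipital_Sup", "Occipital_Mid", "Occipital_Inf",
    "Fusiform", "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

#: 90 labels in standard AAL order: (left, right) per anatomical structure.
AAL90_LABELS: list[str] = []
for _name in _PAIRS:
    AAL90_LABELS.append(f"{_name}_L")
    AAL90_LABELS.append(f"{_name}_R")

# Region 24 (1-based) is the right superior medial frontal gyrus, region 55
# the left fusiform gyrus -- the two nodes this package's synthetic effects
# target by default.
SFGMED_R = 24
FUSIFORM_L = 55

assert AAL90_LABELS[SFGMED_R - 1] == "Frontal_Sup_Medial_R"
assert AAL90_LABELS[FUSIFORM_L - 1] == "Fusiform_L"


def default_labels(n_regions: int) -> list[str]:
    """Region labels for an ``n_regions`` parcellation.

    The 90-region case gets real AAL names; other sizes get ``ROI_001``-style
    placeholders so the machinery stays label-addressed at any size.
    """
    if n_regions == 90:
        return list(AAL90_LABELS)
    return [f"ROI_{i + 1:03d}" for i in range(n_regions)]
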