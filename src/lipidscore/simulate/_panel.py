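"""Random species-panel construction shared by the cohort generators."""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from ..nomenclature import CHAIN_COUNT, LipidClass, parse_lipid_name

# plausible acyl chain inventory (carbons, double bonds)
_CHAIN_POOL = [
    (12, 0), (13, 0), (14, 0), (14, 1), (15, 0), (15, 1), (16, 0),
    (16, 1), (16, 2), (17, 0), (17, 1), (18, 0), (18, 1), (18, 2),
    (18, 3), (19, 0), (19, 1), (20, 0), (20, 1), (20, 2), (20, 3),
    (20, 4), (20, 5), (21, 0), (22, 0), (22, 1), (22, 4), (22, 5),
    (22, 6), (24, 0), (24, 1), (26, 0), (26, 1),
]


def build_panel(species_counts: Dict[str, int], fixed: Sequence[str],
                rng: np.random.Generator) -> List[str]:
    """Return a list of unique canonical labels per class.

    ``fixed`` labels are always included and count toward their class quota.
    """
    fixed_by_class: Dict[str, List[str]] = {}
    for lab in fixed:
        name = parse_lipid_name(lab)
        fixed_by_class.setdefault(name.lipid_class.value, []).append(name.format())

    panel: List[str] = []
    pool = np.array(_CHAIN_POOL)
    for cls_name, count in species_counts.items():
        cls = LipidClass(cls_name)
        arity = CHAIN_COUNT[cls]
        labels = list(dict.fromkeys(fixed_by_class.get(cls_name, [])))
        if len(labels) > count:
            raise ValueError(
                f"{cls_name}: {len(labels)} fixed species exceed quota {count}")
        seen = set(labels)
        attempts = 0
        while len(labels) < count:
            attempts += 1
            if attempts > 100 * count + 1000:
                raise ValueError(f"cannot build {count} unique {cls_name} species")
            idx = rng.integers(0, len(pool), size=arity)
            chains = tuple(sorted((int(pool[i][0]), int(pool[i][1])) for i in idx))
            body = "_".join(f"{c}:{d}" for c, d in chains)
            lab = f"{cls_name}({body})"
            if lab not in seen:
                seen.add(lab)
                labels.append(lab)
        panel.extend(labels)
    return panel
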