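"""Running the pipeline on the published genome-scale reconstructions.

The analyses in this package were designed around the genome-scale yeast
models iBB814 (S. stipitis) and iMM904 (S. cerevisiae).  Those files are
not bundled; download them (e.g. the BiGG JSON of iMM904, or the SBML
supplementary of iBB814) into ./models/ and this script runs the batch
anchors: maximal growth of iBB814 at glucose uptake 4.45 with unbounded
oxygen, and the iMM904 ethanol envelope at glucose 14.08 with O2 <= 2.8
printed against the literature anchors 0.40 1/h and 19.90 mmol/gDW/h.
"""

from pathlib import Path

from redoxplane import (
    fba,
    load_model,
    production_envelope,
    remove_loops,
    set_uptake,
)
from redoxplane.phaseplane import (
    ETHANOL_STEMS,
    GLUCOSE_STEMS,
    OXYGEN_STEMS,
    find_exchange,
)

MODELS = Path(__file__).resolve().parent.parent / "models"


def find(stem):
    for p in sorted(MODELS.glob(f"{stem}*")):
        if p.suffix in (".xml", ".sbml", ".json"):
            return p
    return None


path = find("iBB814")
if path is None:
    print("iBB814 not found under ./models/ - skipping the growth anchor")
else:
    m = load_model(path)
    m = set_uptake(m, find_exchange(m, GLUCOSE_STEMS), 4.45)
    m = set_uptake(m, find_exchange(m, OXYGEN_STEMS), "unbounded")
    sol = fba(m, check_degeneracy=False)
    clean = remove_loops(m, sol)
    print(f"iBB814 max growth at glc 4.45: {sol.objective:.3f} 1/h "
          f"(loop-removed: {clean.objective:.3f})")

path = find("iMM904")
if path is None:
    print("iMM904 not found under ./models/ - skipping the envelope anchor")
else:
    m = load_model(path)
    m = set_uptake(m, find_exchange(m, GLUCOSE_STEMS), 14.08)
    m = set_uptake(m, find_exchange(m, OXYGEN_STEMS), 2.8)
    env = production_envelope(m, find_exchange(m, ETHANOL_STEMS))
    print(f"iMM904 envelope at glc 14.08, O2<=2.8: growth {env.max_growth:.3f} "
          f"1/h, ethanol {env.min_product[-1]:.2f}-{env.max_product[-1]:.2f} "
          f"mmol/gDW/h (anchors: 0.40 1/h, 19.90 mmol/gDW/h)")
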