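#!/usr/bin/env python
"""Repeat anatomy: segment an idealized ankyrin domain, label its
secondary-structure elements, and quantify helix/hairpin composition.

Findings printed at the end; tables under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from ankylotherm.repeats import (
    assign_elements, composition_profile, enrichment, segment_repeats,
    template_labels,
)
from ankylotherm.structures import ResidueSequence, extract_sequence
from ankylotherm.synthetic import RepeatGeometrySpec, make_repeat_structure

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

# a 7-repeat idealized domain with Notch-style author numbering
spec = RepeatGeometrySpec(n_repeats=7, start_number=1872)
model = make_repeat_structure(spec)
seq = extract_sequence(model, "A")
ann = assign_elements(segment_repeats(seq), model, "A")

pd.DataFrame(
    [{"repeat": r.index, "start": r.span[0], "end": r.span[1],
      "score": round(r.score, 2)} for r in ann.repeats]
).to_csv(OUT / "01_repeats.tsv", sep="\t", index=False)

# composition by element class, and an alanine-rich vs generic contrast
labels = [lab for r in ann.repeats for lab in r.element_labels]
helix = composition_profile(seq, labels, "α-helix")
hairpin = composition_profile(seq, labels, "β-hairpin")
pd.DataFrame({"helix": pd.Series(helix.frequencies),
              "hairpin": pd.Series(hairpin.frequencies)}
             ).fillna(0).round(4).to_csv(OUT / "01_composition.tsv", sep="\t")

ala_rich = ResidueSequence(
    "ala_rich", "DKDG" + "AAAALKAA" + "NT" + "AAHLAAKEGA" + "LEVVKDNGR")
generic = ResidueSequence("generic", "DNEGNTPLHLAAKEGHLEIVQLLLKAGADVNAR")
tl = template_labels()
e = enrichment(composition_profile(ala_rich, tl, "α-helix"),
               composition_profile(generic, tl, "α-helix"))
pd.Series(e.entries).round(3).to_csv(OUT / "01_helix_enrichment.tsv", sep="\t")

print(f"segmented {ann.n_repeats} repeats over {seq.numbering[0]}-"
      f"{seq.numbering[-1]}, residual {len(ann.residual)} residues")
print(f"helix alanine frequency {helix.frequencies.get('A', 0):.3f} over "
      f"{helix.n} residues; hairpin n={hairpin.n}")
print(f"alanine log2 enrichment (rich vs generic helices): "
      f"{e.entries['A']:+.2f}")
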