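"""Predict tags on a contig, anchor mapped tags, measure gene distances.

Digests a synthetic contig in silico with PstI-MseI, splices two of the
expected tags into a second 'assembly' contig, anchors them, and reports
the distance from a gene's CDS 5' end to the nearest anchored tag.
"""

import numpy as np
import pandas as pd

from gbsmap.anchor import anchor_tags, gene_marker_distances, in_silico_digest
from gbsmap.enzymes import PSTI_MSEI
from gbsmap.seqs import revcomp

rng = np.random.default_rng(13)
contig = "".join("ACGT"[i] for i in rng.integers(0, 4, size=50_000))
tags = in_silico_digest(contig, PSTI_MSEI, read_len=100, contig_id="ctg0001")
print(f"in silico digest of a 50 kb contig: {len(tags)} expected tags")
sizes = [t.fragment_length for t in tags]
print(f"fragment sizes {min(sizes)}-{max(sizes)} bp "
      f"(size selection window {PSTI_MSEI.min_fragment_bp}-{PSTI_MSEI.max_fragment_bp})")

# pretend two of these tags were genetically mapped; anchor them onto an
# assembly that contains them once forward and once reverse-complemented
mapped = {f"tag{i}": t.seq for i, t in enumerate(tags[:2])}
assembly = {
    "scaffold_1": contig[:20_000],
    "scaffold_2": "".join("ACGT"[i] for i in rng.integers(0, 4, size=5_000))
                  + revcomp(mapped["tag1"])
                  + "".join("ACGT"[i] for i in rng.integers(0, 4, size=5_000)),
}
anchors = anchor_tags(mapped, assembly, max_mismatches=0)
for a in anchors:
    print(f"  {a.tag_id} -> {a.contig}:{a.position} ({a.strand}), "
          f"{a.mismatches} mismatches")

genes = pd.DataFrame([
    {"contig": "scaffold_1", "start": 3_000, "end": 4_200, "strand": "+", "name": "geneA"},
])
table, hist = gene_marker_distances(genes, anchors, bin_width_bp=1_000)
print(table.to_string(index=False))
# distance_bp is measured from the CDS 5' end to the nearest anchored tag
# (0 when a tag lies inside the gene interval).
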