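"""Find the SECIS hairpin downstream of a recoded UGA codon.

Builds one synthetic selenoprotein gene (in-frame TGA followed by a
perfect-stem hairpin inside the coding sequence), calls its ORF with
the opal readthrough table and scans the window after the recoded
codon.  The hit's offset and stem size match the planted values.
"""

import numpy as np

from gcescan.secis import find_hairpin, scan_secis
from gcescan.seqcore import Contig, TranslationTable, find_orfs
from gcescan.synthetic import PlantSpec, _build_selenoprotein, random_dna

spec = PlantSpec(seed=8)
rng = np.random.default_rng(8)
feat = _build_selenoprotein(rng, spec, "demo_seleno", True)
contig = Contig("c", random_dna(rng, 200, 0.41) + feat.dna + random_dna(rng, 200, 0.41))

genes = find_orfs(contig, TranslationTable.opal())
gene = next(g for g in genes if any(
    e.protein_pos == feat.attrs["uga_protein_pos"] for e in g.readthrough_events))
print(f"gene {gene.gene_id}: {len(gene.protein)} aa, selenocysteine at "
      f"residue {gene.readthrough_events[0].protein_pos} "
      f"(planted at {feat.attrs['uga_protein_pos']})")

hits = scan_secis(gene, contig)
for h in hits:
    print(f"SECIS hit: {h.offset_nt} nt after the UGA (planted "
          f"{feat.attrs['secis_offset']}), stem {h.stem_bp} bp, loop "
          f"{h.loop_nt} nt, {h.mismatches} mismatches, score {h.score}")

# the same search on a shuffled window finds nothing comparable
upos = feat.attrs["uga_protein_pos"]
window = feat.dna[3:][3 * upos :][:75]
shuffled = "".join(rng.permutation(list(window)))
hp = find_hairpin(shuffled)
print(f"best hairpin in a shuffled window: "
      f"{'score %d' % hp.score if hp else 'none'} (threshold is 28)")
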