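"""Fold and classify the three tRNA structural classes.

Constructs a canonical tRNA, a Pyl tRNA (CUA anticodon, 6-bp anticodon
stem, 1-nt acceptor-to-D spacer) and a Sec tRNA (UCA anticodon, long
variable arm), refolds each from sequence alone and prints the
recovered cloverleaf layout and class.
"""

import numpy as np

from gcescan.synthetic import PlantSpec, _build_trna
from gcescan.trna import TRNACandidate, anticodon_of, classify_trna, fold_cloverleaf

spec = PlantSpec()
rng = np.random.default_rng(4)
for kind, anticodon_dna in (("standard", "GAA"), ("pyl", "CTA"), ("sec", "TCA")):
    feat = _build_trna(rng, spec, kind, kind, anticodon_dna)
    layout, score, gu = fold_cloverleaf(feat.dna)
    cand = TRNACandidate("demo", 1, len(feat.dna), "+",
                         anticodon_of(feat.dna, layout), layout, score, gu)
    print(f"{kind:8s} {len(feat.dna):3d} nt  anticodon {cand.anticodon}  "
          f"pair_score {score} ({gu} wobble)  -> class {classify_trna(cand)}")
    print(f"         acceptor {layout.acceptor_bp} bp | spacer "
          f"{layout.spacer_nt} nt | D {layout.d_stem_bp} bp/"
          f"{layout.d_loop_nt} nt | anticodon stem {layout.ac_stem_bp} bp | "
          f"variable {layout.var_nt} nt"
          f"{' (arm)' if layout.var_is_arm else ' (loop)'} | "
          f"T {layout.t_stem_bp} bp/{layout.t_loop_nt} nt")
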