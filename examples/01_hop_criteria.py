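"""What makes a scaffold hop: 2D dissimilarity plus 3D similarity.

Compares a candidate hop (imidazopyridazine-like to triazolopyridine-like
swap, here stood in by pyridine vs pyrimidine cores) against a trivial
R-group edit on the three pair criteria.
"""

from deephop import chem

x = chem.embed_conformers(chem.canonicalize("Cc1ccc(O)nc1", "seed"), n_conf=10)
hop = chem.embed_conformers(chem.canonicalize("Cc1ncc(O)cn1", "hop"), n_conf=10)
edit = chem.embed_conformers(chem.canonicalize("CCc1ccc(O)nc1", "edit"), n_conf=10)

for name, y in [("core swap", hop), ("R-group edit", edit)]:
    s2 = chem.scaffold_similarity_2d(x, y)
    s3 = chem.sc_score(x, y)
    is_hop = s2 <= 0.6 and s3 >= 0.6
    print(f"{name:12s} scaffold X={chem.bm_scaffold(x).smiles} "
          f"Y={chem.bm_scaffold(y).smiles}")
    print(f"{'':12s} 2D scaffold Tanimoto = {s2:.3f}  (hop needs <= 0.6)")
    print(f"{'':12s} 3D shape+color score = {s3:.3f}  (hop needs >= 0.6)")
    print(f"{'':12s} structural hop: {is_hop}\n")

print("A hop changes the ring framework (low 2D similarity) while keeping")
print("the 3D presentation (high SC score); an R-group edit keeps both high,")
print("so it fails the 2D-dissimilarity criterion.")
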