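"""Conservation scores from a reference-anchored alignment.

Writes a tiny A3M alignment (lowercase = insertion relative to the
reference profile), filters homologs at 20% identity, and computes the
per-position conservation score CS = matches / non-gap homolog residues.
"""

import tempfile
from pathlib import Path

from idrscape import conservation_scores, filter_homologs, parse_alignment

A3M = """>query
GYSKAGYSKA
>hom1
GYSKAGYSKA
>hom2
GYsSTAGY-KA
>hom3
G---------
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.a3m"
    path.write_text(A3M)
    aln = parse_alignment(path)

print(f"homologs before identity filter: {len(aln)}")
aln = filter_homologs(aln, min_identity=0.20)
print(f"homologs with >= 20% identity:  {len(aln)}")

track = conservation_scores(aln)
print()
print(track.to_string(index=False))
print()
print("cs = 1.0 means every aligned homolog keeps the reference residue;")
print("the insertion (lowercase s in hom2) was removed during parsing, so")
print("columns stay in reference coordinates.")
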