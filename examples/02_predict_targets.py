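"""Score miRNA target sites on a transcript, psRNATarget-style.

Plants a perfect complementary site and a near-perfect site with one
central mismatch, then scans for targets with the default expectation
cutoff of 3 and classifies each site's inhibition mode.
"""

import random

from mirframe import SequenceRecord, predict_targets
from mirframe.io_formats import reverse_complement

rng = random.Random(7)
mirna = "UGACAGAAGAGAGUGAGCACA"

perfect = reverse_complement(mirna)
central = list(perfect)
# a non-pairing base facing miRNA position 10 (inside the 9-11 window)
central[len(mirna) - 10] = {"A": "G", "C": "A", "G": "G", "U": "C"}[mirna[9]]
background = lambda n: "".join(rng.choice("ACGU") for _ in range(n))
transcript = SequenceRecord(
    id="mRNA1",
    sequence=background(80) + perfect + background(40) + "".join(central) + background(80),
)

hits = predict_targets({"miR-x": mirna}, [transcript])
print(f"{len(hits)} sites under expectation <= 3:")
for h in hits:
    print(
        f"  {h.transcript_id} {h.site_start + 1}-{h.site_end}  "
        f"expectation {h.expectation:.1f}  {h.mode}\n"
        f"    miRNA 5'-{mirna}-3'\n"
        f"{' ' * 13}{h.alignment_string()}"
    )
print(
    "\nExpectation 0 = perfect complementarity (cleavage); the central"
    "\nmismatch at position 10 doubles to 2.0 and flips the mode to"
    "\ntranslational inhibition."
)
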