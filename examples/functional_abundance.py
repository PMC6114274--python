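"""Functional abundance profiling of annotated samples.

Maps accepted domains to GO classes via a pfam2go table and computes the
two normalisations: within-sample (relative to the most represented
class) and cross-sample N^S_I (domains per megabase scaled by the
average sample size).
"""

import tempfile
from pathlib import Path

from cladescan.functional_profile import (
    class_counts,
    cross_sample_abundance,
    load_pfam2go,
    within_sample_normalise,
)
from cladescan.search_backend import DomainHit
from cladescan.seqio import ReadAnnotation

pfam2go_text = """!pfam2go example
Pfam:PF00001 7tm_1 > GO:G-protein coupled receptor activity ; GO:0004930
Pfam:PF00001 7tm_1 > GO:signal transduction ; GO:0007165
Pfam:PF00005 ABC_tran > GO:ATP binding ; GO:0005524
"""
with tempfile.NamedTemporaryFile("w", suffix=".txt", delete=False) as fh:
    fh.write(pfam2go_text)
mapping = load_pfam2go(fh.name)
Path(fh.name).unlink()


def hit(rid, acc):
    return DomainHit(read_id=rid, model_id=f"{acc}_SCM", domain_acc=acc, model_type="SCM",
                     ali_start=1, ali_end=30, bit_score=40.0, mean_bit_score=40 / 30)


annos = [
    ReadAnnotation("r1", hits=[hit("r1", "PF00001")]),
    ReadAnnotation("r2", hits=[hit("r2", "PF00001")]),
    ReadAnnotation("r3", hits=[hit("r3", "PF00005")]),
]
counts = class_counts(annos, mapping)
print("class counts:", counts)
print("within-sample normalised:", within_sample_normalise(counts))
# each value is the class count divided by the sample's top class.

n_si = cross_sample_abundance(count=100, sample_size_mb=2.0, all_sizes_mb=[2.0, 6.0])
print(f"N^S_I for 100 domains in a 2 Mb sample (samples of 2 and 6 Mb): {n_si}")
# (100/2) domains per Mb x 4 Mb average size = 200 expected domains at
# the common sample size.
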