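"""Using real search-engine output instead of the built-in scanner.

The selection pipeline is engine-agnostic: hits parsed from an HMMER3
``--domtblout`` file (consensus models) or a PSI-BLAST tabular file
(clade-centered models) carry the same (bit-score, mean-bit-score)
coordinates and flow through the same filters.
"""

import tempfile
from pathlib import Path

from cladescan.model_library import DomainModel, ModelLibrary
from cladescan.search_backend import parse_domtblout, parse_psiblast_tabular

lib = ModelLibrary()
lib.add(DomainModel("PF01036_SCM", "PF01036", "SCM", "", "M" * 40))
lib.add(DomainModel("PF01036_actino", "PF01036", "CCM", "Actinobacteria", "M" * 40))

domtbl = (
    "# target name        accession tlen query name accession qlen E-value score bias "
    "# of c-Evalue i-Evalue score bias hmm_from hmm_to ali_from ali_to env_from env_to acc desc\n"
    "PF01036_SCM - 240 read_042 - 60 1.2e-08 36.2 0.1 1 1 2e-08 1.5e-08 36.2 0.1 5 40 5 40 5 40 0.92 -\n"
)
with tempfile.NamedTemporaryFile("w", suffix=".domtblout", delete=False) as fh:
    fh.write(domtbl)
hits = parse_domtblout(fh.name, lib)
Path(fh.name).unlink()
for h in hits:
    print(f"domtblout hit: {h.read_id} {h.model_id} {h.ali_start}-{h.ali_end} "
          f"bit={h.bit_score} mean_bit={h.mean_bit_score:.3f}")
# the mean-bit-score (bits per aligned residue) is the second axis of
# the 2-D gathering threshold.

psiblast = "PF01036_actino\tread_099\t82.35\t34\t6\t0\t1\t34\t12\t45\t3.2e-05\t41.5\n"
with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
    fh.write(psiblast)
hits = parse_psiblast_tabular(fh.name, lib)
Path(fh.name).unlink()
for h in hits:
    print(f"psiblast hit:  {h.read_id} {h.model_id} {h.ali_start}-{h.ali_end} "
          f"bit={h.bit_score} identity={h.identity_pct}%")
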