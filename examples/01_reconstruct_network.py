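"""Reconstruct an arc network from a KEGG-style input bundle.

Writes the toy bundle to a temporary directory, runs the full
reconstruction (parse -> filter -> reversibility split -> arcs ->
metabolite categories) and prints the log. The four RX records exercise
the exclusion rules; R6 (ΔrG'm = +5 kJ/mol, below the 15 kJ/mol
threshold) is split into a reversible pair.
"""

import tempfile
from pathlib import Path

from arcpath import io as aio
from arcpath.fixtures import make_fig3_bundle, write_kegg_fixture
from arcpath.network import reconstruct_network

with tempfile.TemporaryDirectory() as tmp:
    bundle_dir = write_kegg_fixture(make_fig3_bundle(), Path(tmp) / "bundle")
    masses, names, generic = aio.read_compounds_tsv(bundle_dir / "compounds.tsv")
    network, log = reconstruct_network(
        (bundle_dir / "reactions.keg").read_text(),
        aio.read_pairs_tsv(bundle_dir / "pairs.tsv"),
        aio.read_thermo_tsv(bundle_dir / "thermo.tsv"),
        masses,
        basis_list=aio.read_id_list(bundle_dir / "basis.txt"),
    )

for line in log.lines():
    print(line)
print()
print("arcs (substrate -> product via reaction):")
for arc in sorted(network.arcs):
    print(f"  {arc.substrate} -> {arc.product}  via {arc.reaction} [{arc.category}]")
print()
print("metabolite pool (freely available):", ", ".join(sorted(network.categories.pool)))
print("externals (must be net-produced):  ", ", ".join(sorted(network.categories.external)))
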