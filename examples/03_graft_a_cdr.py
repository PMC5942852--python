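"""Graft a database CDR conformation onto an antibody framework.

Takes a fixture antibody, grafts an 11-residue L1 conformation from a
different cluster in place of its 10-residue native loop, and reports
the closure diagnostics.
"""

import numpy as np

from cdrdesign import graft_cdr
from cdrdesign.synthetic import SyntheticSpec, make_synthetic_benchmark

bench = make_synthetic_benchmark(
    SyntheticSpec(n_antibodies=1, entries_per_cdr=8, seed=4))
ab = bench.antibodies["ab000"]
native = bench.native_labels["ab000"]["L1"]
print(f"native L1: cluster {native['cluster']} (length {native['length']})")

donor = next(e for e in bench.entries
             if e.cdr == "L1" and e.cluster_id != native["cluster"])
print(f"donor:     cluster {donor.cluster_id} (length {donor.length}) "
      f"from {donor.source_pdb}")

result = graft_cdr(donor, ab, "L1", rng=np.random.default_rng(0))
geom = result.junction_geometry
print(f"closed: {result.closed}  (fallback: {result.used_fallback}, "
      f"CCD cycles: {result.cycles})")
print(f"C-side junction: C-N {geom.c_terminal.cn_distance:.2f} A, "
      f"CA-C-N {geom.c_terminal.ca_c_n_angle:.1f} deg, "
      f"C-N-CA {geom.c_terminal.c_n_ca_angle:.1f} deg")
print(f"internal CDR RMSD to database conformation: "
      f"{result.internal_rmsd:.3f} A")
# A closed graft keeps the peptide C-N bond under 1.5 A with junction
# angles within 15 degrees of ideal, while the interior of the loop
# stays within a fraction of an Angstrom of the database conformation.
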