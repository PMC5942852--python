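"""A small graft-and-design Monte Carlo run.

Designs L1 of a fixture antibody against its toy CDR database with the
built-in coarse reference energy: 3 trajectories of 10 outer cycles,
profile-guided sequence design over the packing shell, and Metropolis
acceptance on total energy.
"""

from cdrdesign import (CdrSetFilter, ProtocolConfig, ReferenceEnergy,
                       build_profiles, cull_all, query_cdrset, run_design)
from cdrdesign.protocol import score_table
from cdrdesign.synthetic import (SyntheticSpec, default_composition,
                                 make_synthetic_benchmark)

spec = SyntheticSpec(
    n_antibodies=1, entries_per_cdr=16, seed=7,
    composition=default_composition(cdrs=("L1",),
                                    lengths={"L1": (10, 11)}))
bench = make_synthetic_benchmark(spec)
ab = bench.antibodies["ab000"]
entries = cull_all(bench.entries)
cdrset = query_cdrset(entries, CdrSetFilter(min_cluster_members=1),
                      ("L1",), "kappa")
profiles = build_profiles(entries, min_members=3)

config = ProtocolConfig(n_outer=10, n_struct=3, seed=11,
                        graft_design_cdrs=("L1",),
                        seq_design_cdrs=("L1",),
                        random_start=True)
records = run_design(ab, cdrset, ReferenceEnergy(), config, profiles)
print(score_table(records).to_string(index=False))
# One row per trajectory: its best (lowest) acceptance energy, the
# interface energy of that decoy, the L1 cluster it ended with, and
# the designed CDR sequences.  Identical seeds reproduce this table
# byte for byte.
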