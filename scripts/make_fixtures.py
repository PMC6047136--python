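#!/usr/bin/env python
"""Regenerate the committed synthetic example data under fixtures/.

The files are the documented planted-module benchmark: 50 drugs x 40 targets,
4 modules, p_in=0.5, p_out=0.02, similarity signal 0.8, seed 1 (library seed,
i.e. SyntheticSpec(seed=1) directly).
"""

import os

from netlinkpred import write_bipartite_matrix, write_similarity_matrix
from netlinkpred.synthetic import SyntheticSpec, gen_benchmark

HERE = os.path.dirname(os.path.abspath(__file__))
OUT = os.path.join(HERE, "..", "fixtures")


def main() -> None:
    spec = SyntheticSpec(seed=1)
    net, d_sim, t_sim, truth = gen_benchmark(spec)
    os.makedirs(OUT, exist_ok=True)
    write_bipartite_matrix(net, os.path.join(OUT, "interactions.csv"))
    write_similarity_matrix(d_sim, os.path.join(OUT, "drug_sim.csv"))
    write_similarity_matrix(t_sim, os.path.join(OUT, "target_sim.csv"))
    with open(os.path.join(OUT, "modules.tsv"), "w") as fh:
        fh.write("# planted ground-truth modules; spec: 50x40, 4 modules, "
                 "p_in=0.5, p_out=0.02, sim_signal=0.8, seed=1\n")
        fh.write("node\ttype\tmodule\n")
        for lab in net.target_labels:
            fh.write(f"{lab}\ttarget\t{truth[lab]}\n")
        for lab in net.drug_labels:
            fh.write(f"{lab}\tdrug\t{truth[lab]}\n")
    print(f"wrote fixtures to {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
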