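"""Shared test fixtures builders."""

import pandas as pd

from pasfactory.pas_calling import PASCountMatrix


def make_matrix(gene_counts: dict, summits=None):
    """PASCountMatrix from {gene: {pas: [c_ctl..., c_trt...]}} (4v4)."""
    samples = [f"{c}_rep{i}" for c in ("control", "treated") for i in range(1, 5)]
    rows, meta = [], []
    pos = 0
    for gid, pas_dict in gene_counts.items():
        for k, (pid, counts) in enumerate(pas_dict.items()):
            rows.append(counts)
            meta.append({"pas_id": pid, "chrom": "c", "start": pos, "end": pos + 30,
                         "strand": "+",
                         "summit": (summits or {}).get(pid, pos + 15),
                         "gene_id": gid, "summed_signal": float(sum(counts)),
                         "order_index": k + 1})
            pos += 3000
    meta = pd.DataFrame(meta).set_index("pas_id")
    counts = pd.DataFrame(rows, index=meta.index, columns=samples)
    return PASCountMatrix(counts, meta, [], {s: 0 for s in samples}), \
        {s: s.split("_")[0] for s in samples}
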