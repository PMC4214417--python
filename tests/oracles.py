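"""Shared brute-force oracles, independent of the package implementations."""

import numpy as np


def greedy_clump_oracle(p, chrom, pos, dosages, p_thr, r2_thr, window):
    """Exhaustive greedy clumping with inline haplotype-frequency r2."""
    passing = [i for i in range(len(p)) if np.isfinite(p[i]) and p[i] <= p_thr]
    unassigned = set(passing)
    loci = []
    for lead in sorted(passing, key=lambda i: p[i]):
        if lead not in unassigned:
            continue
        unassigned.remove(lead)
        members = [lead]
        for j in list(sorted(unassigned)):
            if chrom[j] != chrom[lead] or abs(pos[j] - pos[lead]) > window:
                continue
            x, z = dosages[:, lead], dosages[:, j]
            ok = np.isin(x, (0.0, 2.0)) & np.isin(z, (0.0, 2.0))
            a, b = x[ok] / 2, z[ok] / 2
            pa, pb, pab = a.mean(), b.mean(), (a * b).mean()
            if pa in (0, 1) or pb in (0, 1):
                continue
            r2 = (pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))
            if r2 > r2_thr:
                members.append(j)
                unassigned.remove(j)
        loci.append((lead, sorted(members)))
    return sorted(loci, key=lambda t: p[t[0]])
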