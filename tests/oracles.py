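"""Independent brute-force recounts used as oracles against the package.

Everything here is written as plain per-site loops over primitive values,
deliberately avoiding the package's phase/count code paths.
"""

import numpy as np
import pandas as pd

from pghaplo import SnpTable


def random_table(rng, n_sites=200, n_embryos=2, depth_hi=40):
    """A random (not necessarily Mendelian) family table for oracle tests."""
    pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=n_sites, replace=False))
    sites = pd.DataFrame(
        {"chrom": "chrX", "pos": pos, "ref": ["G"] * n_sites, "alt": ["A"] * n_sites}
    )

    def hemi_call():
        r = rng.random()
        if r < 0.1:
            return None
        return (int(rng.integers(0, 2)),)

    def diploid_call():
        r = rng.random()
        if r < 0.1:
            return None
        a, b = int(rng.integers(0, 2)), int(rng.integers(0, 2))
        return (min(a, b), max(a, b))

    calls = {
        "father": [hemi_call() for _ in range(n_sites)],
        "mother": [diploid_call() for _ in range(n_sites)],
        "reference": [hemi_call() for _ in range(n_sites)],
    }
    for e in range(1, n_embryos + 1):
        calls[f"Embryo{e}"] = [diploid_call() for _ in range(n_sites)]
    depths = {s: rng.integers(0, depth_hi, size=n_sites).astype(np.int64) for s in calls}
    roles = {s: (s if s in ("father", "mother", "reference") else "embryo") for s in calls}
    return SnpTable(sites=sites, calls=calls, depths=depths, roles=roles)


def brute_filter(table, locus, min_depth):
    """Per-site re-check of the window/depth filter; returns kept indices."""
    lo, hi = locus.window
    keep = []
    for i in range(table.n_sites):
        pos = int(table.sites["pos"].iloc[i])
        if table.sites["chrom"].iloc[i] != locus.chrom or not (lo <= pos <= hi):
            continue
        if any(
            table.depths[s][i] <= min_depth
            for s in (table.father, table.mother, table.reference)
        ):
            continue
        keep.append(i)
    return keep


def brute_phase(table):
    """Site-by-site informativeness classification.

    Returns (maternal, paternal): maternal rows are
    (site_idx, pos, x1, x2, father_allele_or_None, class); paternal rows are
    (site_idx, pos, father_allele, maternal_allele).
    """
    maternal, paternal = [], []
    for i in range(table.n_sites):
        m = table.calls[table.mother][i]
        f = table.calls[table.father][i]
        r = table.calls[table.reference][i]
        pos = int(table.sites["pos"].iloc[i])
        f_allele = f[0] if f is not None and len(set(f)) == 1 else None
        if m is None:
            continue
        if len(set(m)) == 2:
            if r is None or len(r) != 1:
                continue
            x1 = r[0]
            x2 = 1 - x1
            if f_allele is None:
                cls = "male_only"
            elif f_allele != x1:
                cls = "x1_detecting"
            else:
                cls = "x2_detecting"
            maternal.append((i, pos, x1, x2, f_allele, cls))
        elif f_allele is not None and f_allele != m[0]:
            paternal.append((i, pos, f_allele, m[0]))
    return maternal, paternal


def brute_count(table, embryo, maternal, paternal, sex, min_depth):
    """Site-by-site support recount; returns (f_x, m_x1, m_x2, labels)."""
    f_x = m_x1 = m_x2 = 0
    labels = []
    for i, pos, x1, x2, f_allele, cls in maternal:
        g = table.calls[embryo][i]
        if g is None or table.depths[embryo][i] <= min_depth:
            labels.append((pos, "no-call"))
            continue
        alleles = set(g)
        label = "ambiguous"
        if sex == "M":
            if len(alleles) == 1:
                label = "X1" if alleles == {x1} else "X2"
        else:
            if cls != "male_only":
                if len(alleles) == 2:
                    residual = (alleles - {f_allele}).pop()
                    label = "X1" if residual == x1 else "X2"
                elif alleles != {f_allele}:
                    label = "X1" if alleles == {x1} else "X2"
        if label == "X1":
            m_x1 += 1
        elif label == "X2":
            m_x2 += 1
        labels.append((pos, label))
    for i, pos, f_allele, m_allele in paternal:
        g = table.calls[embryo][i]
        if g is not None and table.depths[embryo][i] > min_depth and f_allele in g:
            f_x += 1
    return f_x, m_x1, m_x2, labels
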