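"""Independent brute-force oracles shared by unit and acceptance tests."""

import numpy as np


# ---------------------------------------------------------------------------
# Brute-force split-plot oracle: explicit summation over cells, Type III
# effect sums of squares obtained by direct least squares on sum-coded
# dummies built by hand (no shared code with the implementation).

def _oracle_mixed_anova(Y, groups):
    Y = np.asarray(Y, dtype=float)
    N, C = Y.shape
    glabels = sorted(set(groups))
    gidx = np.array([glabels.index(g) for g in groups])
    G = len(glabels)

    def design(cols):
        rows = []
        for s in range(N):
            for c in range(C):
                row = [1.0]
                gcode = [0.0] * (G - 1)
                if gidx[s] < G - 1:
                    gcode[gidx[s]] = 1.0
                else:
                    gcode = [-1.0] * (G - 1)
                ccode = [0.0] * (C - 1)
                if c < C - 1:
                    ccode[c] = 1.0
                else:
                    ccode = [-1.0] * (C - 1)
                icode = [a * b for a in gcode for b in ccode]
                if "g" in cols:
                    row += gcode
                if "c" in cols:
                    row += ccode
                if "i" in cols:
                    row += icode
                rows.append(row)
        return np.array(rows)

    yv = Y.reshape(-1)

    def sse(X):
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        return ((yv - X @ beta) ** 2).sum()

    full = sse(design("gci"))
    ss_g = sse(design("ci")) - full
    ss_c = sse(design("gi")) - full
    ss_i = sse(design("gc")) - full

    subj_means = Y.mean(axis=1)
    ss_subj = 0.0
    for g in range(G):
        mg = subj_means[gidx == g].mean()
        for s in np.flatnonzero(gidx == g):
            ss_subj += C * (subj_means[s] - mg) ** 2
    ss_resid = 0.0
    for g in range(G):
        sel = np.flatnonzero(gidx == g)
        gmean = Y[sel].mean()
        for c in range(C):
            cell = Y[sel, c].mean()
            for s in sel:
                ss_resid += (Y[s, c] - subj_means[s] - cell + gmean) ** 2
    ms_subj = ss_subj / (N - G)
    ms_resid = ss_resid / ((N - G) * (C - 1))
    return (
        (ss_g / (G - 1)) / ms_subj,
        (ss_c / (C - 1)) / ms_resid,
        (ss_i / ((G - 1) * (C - 1))) / ms_resid,
    )
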