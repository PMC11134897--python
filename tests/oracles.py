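"""Independent brute-force reference implementations used only by tests.

Every function here is written as a direct loop over definitions so that the
vectorised package code is checked against an implementation that shares no
code path with it.
"""
import math
from statistics import median


def time_domain_loop(values):
    n = len(values)
    total = 0.0
    for v in values:
        total += v
    mean_nn = total / n
    ss = 0.0
    for v in values:
        ss += (v - mean_nn) ** 2
    sdnn = math.sqrt(ss / (n - 1))
    count = 0
    for i in range(n - 1):
        if abs(values[i + 1] - values[i]) > 50.0:
            count += 1
    pnn50 = 100.0 * count / (n - 1)
    return mean_nn, 60000.0 / mean_nn, sdnn, pnn50


def poincare_loop(values):
    us, vs = [], []
    for i in range(len(values) - 1):
        us.append((values[i + 1] - values[i]) / math.sqrt(2.0))
        vs.append((values[i + 1] + values[i]) / math.sqrt(2.0))

    def sample_sd(xs):
        m = sum(xs) / len(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))

    return sample_sd(us), sample_sd(vs)


def auc_paircount(scores, labels):
    """Tie-corrected pair counting: (#concordant + 0.5 * #tied) / (n1 * n0)
    for the orientation 'cases score higher'."""
    cases = [s for s, y in zip(scores, labels) if y]
    controls = [s for s, y in zip(scores, labels) if not y]
    conc = ties = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                conc += 1.0
            elif c == k:
                ties += 1.0
    return (conc + 0.5 * ties) / (len(cases) * len(controls))


def clean_rules_loop(values, labels, w=11, threshold=0.20, lo=300.0, hi=2000.0):
    """Re-evaluate exclusion rules (a)-(c) interval by interval; returns the
    resulting label list."""
    out = []
    recent = []
    for x, lab in zip(values, labels):
        if lab in ("ectopic", "artifact"):
            out.append(lab)
            continue
        if not (lo <= x <= hi):
            out.append("artifact")
            continue
        if len(recent) >= w:
            med = median(recent[-w:])
            if abs(x - med) > threshold * med:
                out.append("artifact")
                continue
        out.append("normal")
        recent.append(x)
    return out


def min_sdnn_start_loop(values, start_times, labels, L, skip_s):
    """Brute-force scan over all candidate NN windows; returns the index (into
    the original series) of the first interval of the selected window."""
    eligible = [i for i, (t, lab) in enumerate(zip(start_times, labels))
                if lab == "normal" and t >= skip_s]
    best = None
    best_sd = None
    for p in range(len(eligible) - L + 1):
        window = [values[i] for i in eligible[p:p + L]]
        m = sum(window) / L
        sd = math.sqrt(sum((x - m) ** 2 for x in window) / (L - 1))
        if best_sd is None or sd < best_sd:
            best_sd = sd
            best = eligible[p]
    return best


def rm_anova_ss_loop(matrix):
    """Sum-of-squares decomposition for a subjects x conditions matrix."""
    n = len(matrix)
    k = len(matrix[0])
    grand = sum(sum(row) for row in matrix) / (n * k)
    ss_total = sum((x - grand) ** 2 for row in matrix for x in row)
    ss_subj = k * sum((sum(row) / k - grand) ** 2 for row in matrix)
    col_means = [sum(matrix[i][j] for i in range(n)) / n for j in range(k)]
    ss_cond = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_resid = ss_total - ss_subj - ss_cond
    f = (ss_cond / (k - 1)) / (ss_resid / ((k - 1) * (n - 1)))
    return f
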