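"""Independent brute-force oracles for the feature encoders and metrics.

Every function here is a literal, loop-based transcription of the defining
sums — deliberately unvectorized and sharing no code with the package
implementation — so agreement between the two routes is meaningful.
"""

import itertools
import math

BASES = "ACGT"
DINUCS = ["".join(p) for p in itertools.product(BASES, repeat=2)]
TRINUCS = ["".join(p) for p in itertools.product(BASES, repeat=3)]
EIIP_MONO = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}


def oracle_standardize(table):
    """table: {oligo: {index: value}} -> standardized copy (population SD)."""
    oligos = sorted(table)
    names = list(table[oligos[0]])
    out = {o: {} for o in oligos}
    for name in names:
        vals = [table[o][name] for o in oligos]
        mu = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / len(vals))
        for o in oligos:
            out[o][name] = (table[o][name] - mu) / sd
    return out


def oracle_one_hot(seq, pad_to=99):
    codes = {"A": [1, 0, 0, 0], "C": [0, 1, 0, 0],
             "G": [0, 0, 1, 0], "T": [0, 0, 0, 1]}
    rows = [codes.get(b, [0, 0, 0, 0]) for b in seq]
    while len(rows) < pad_to:
        rows.append([0, 0, 0, 0])
    return rows


def oracle_ncp(seq, pad_to=99):
    rows = []
    for b in seq:
        if b not in BASES:
            rows.append([0, 0, 0])
            continue
        rows.append([
            1 if b in "AC" else 0,
            1 if b in "AG" else 0,
            1 if b in "AT" else 0,
        ])
    while len(rows) < pad_to:
        rows.append([0, 0, 0])
    return rows


def oracle_kmer(seq, k):
    windows = [seq[i:i + k] for i in range(len(seq) - k + 1)]
    windows = [w for w in if_valid(windows)]
    counts = {t: 0 for t in ("".join(p) for p in itertools.product(BASES, repeat=k))}
    for w in windows:
        counts[w] += 1
    return [counts[t] / len(windows) for t in sorted(counts)]


def if_valid(windows):
    for w in windows:
        if all(b in BASES for b in w):
            yield w


def oracle_pseeiip(seq):
    f = oracle_kmer(seq, 3)
    out = []
    for t, ft in zip(TRINUCS, f):
        out.append((EIIP_MONO[t[0]] + EIIP_MONO[t[1]] + EIIP_MONO[t[2]]) * ft)
    return out


def _theta_oracle(seq, std_table, lam, k):
    """Correlation factors theta_1..theta_lam on k-mer windows."""
    names = list(std_table[sorted(std_table)[0]])
    wins = [seq[i:i + k] for i in range(len(seq) - k + 1)]
    thetas = []
    for j in range(1, lam + 1):
        terms = []
        for i in range(len(wins) - j):
            a, b = wins[i], wins[i + j]
            s = 0.0
            for name in names:
                s += (std_table[a][name] - std_table[b][name]) ** 2
            terms.append(s / len(names))
        thetas.append(sum(terms) / len(terms))
    return thetas


def oracle_psednc(seq, raw_table, lam, w):
    std = oracle_standardize(raw_table)
    freqs = oracle_kmer(seq, 2)
    thetas = _theta_oracle(seq, std, lam, 2)
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def oracle_pcpsetnc(seq, raw_table_tri, lam, w):
    std = oracle_standardize(raw_table_tri)
    freqs = oracle_kmer(seq, 3)
    thetas = _theta_oracle(seq, std, lam, 3)
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def oracle_pseknc(seq, raw_table, k, lam, w):
    std = oracle_standardize(raw_table)
    freqs = oracle_kmer(seq, k)
    thetas = _theta_oracle(seq, std, lam, 2)
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def _profile_oracle(seq, std_table, k):
    names = list(std_table[sorted(std_table)[0]])
    wins = [seq[i:i + k] for i in range(len(seq) - k + 1)]
    return {name: [std_table[w][name] for w in wins] for name in names}, names


def oracle_dac(seq, raw_table, max_lag):
    std = oracle_standardize(raw_table)
    prof, names = _profile_oracle(seq, std, 2)
    out = []
    for name in names:
        x = prof[name]
        pbar = sum(x) / len(x)
        for lag in range(1, max_lag + 1):
            terms = []
            for i in range(len(x) - lag):
                terms.append((x[i] - pbar) * (x[i + lag] - pbar))
            out.append(sum(terms) / len(terms))
    return out


def oracle_dcc(seq, raw_table, max_lag):
    std = oracle_standardize(raw_table)
    prof, names = _profile_oracle(seq, std, 2)
    out = []
    for n1 in names:
        for n2 in names:
            if n1 == n2:
                continue
            x1, x2 = prof[n1], prof[n2]
            m1 = sum(x1) / len(x1)
            m2 = sum(x2) / len(x2)
            for lag in range(1, max_lag + 1):
                terms = []
                for i in range(len(x1) - lag):
                    terms.append((x1[i] - m1) * (x2[i + lag] - m2))
                out.append(sum(terms) / len(terms))
    return out


def oracle_dacc(seq, raw_table, max_lag):
    return oracle_dac(seq, raw_table, max_lag) + oracle_dcc(seq, raw_table, max_lag)


def oracle_moran(seq, raw_table, max_lag):
    std = oracle_standardize(raw_table)
    prof, names = _profile_oracle(seq, std, 2)
    out = []
    for name in names:
        x = prof[name]
        xbar = sum(x) / len(x)
        var = sum((v - xbar) ** 2 for v in x) / len(x)
        for lag in range(1, max_lag + 1):
            if var < 1e-30:
                out.append(0.0)
                continue
            terms = []
            for i in range(len(x) - lag):
                terms.append((x[i] - xbar) * (x[i + lag] - xbar))
            out.append((sum(terms) / len(terms)) / var)
    return out


# ---------------------------------------------------------------------------
# metrics oracles
# ---------------------------------------------------------------------------

def oracle_confusion(y_true, y_pred):
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def oracle_metrics(y_true, y_pred):
    tp, tn, fp, fn = oracle_confusion(y_true, y_pred)
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return {"acc": acc, "sn": sn, "sp": sp, "mcc": mcc,
            "precision": prec, "recall": sn}


def oracle_auroc(y_true, scores):
    """Pairwise comparison: P(random positive outscores random negative)."""
    wins = 0.0
    n_pairs = 0
    for i, (ti, si) in enumerate(zip(y_true, scores)):
        if ti != 1:
            continue
        for tj, sj in zip(y_true, scores):
            if tj != 0:
                continue
            n_pairs += 1
            if si > sj:
                wins += 1.0
            elif si == sj:
                wins += 0.5
    return wins / n_pairs
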