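"""Independent reference implementations used to check the package's
statistics and translation code.  These deliberately avoid the code paths
under test: exact integer hypergeometric enumeration, the closed-form
Welch/pooled t-test, and a plain codon-loop translator."""

import math

from scipy.special import stdtr

# --- exact one-sided Fisher test by hypergeometric enumeration ------------


def fisher_greater_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the 2x2 table [[a, b], [c, d]] with fixed margins,
    by direct integer enumeration of the hypergeometric pmf."""
    n_row1 = a + b
    k_col1 = a + c
    n_total = a + b + c + d
    denom = math.comb(n_total, n_row1)
    num = 0
    upper = min(n_row1, k_col1)
    for x in range(a, upper + 1):
        num += math.comb(k_col1, x) * math.comb(n_total - k_col1, n_row1 - x)
    return num / denom


# --- closed-form two-sample t-test ----------------------------------------


def t_test_closed_form(x, y, equal_var=False, alternative="two-sided"):
    """p-value via the textbook t statistic and Student-t CDF (scipy's
    stdtr special function, not scipy.stats.ttest_ind)."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    if equal_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = math.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
    else:
        se = math.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    t = (mx - my) / se
    if alternative == "two-sided":
        return 2 * (1 - stdtr(df, abs(t)))
    if alternative == "greater":
        return 1 - stdtr(df, t)
    return stdtr(df, t)


# --- naive codon-loop translation -----------------------------------------

_BASES = "TCAG"
_TABLE1 = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
           "VVVVAAAADDEEGGGG")
CODON_TABLE = {a + b + c: _TABLE1[i]
               for i, (a, b, c) in enumerate(
                   (a, b, c) for a in _BASES for b in _BASES for c in _BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def naive_translate(nt: str) -> str:
    """Straight codon-loop translation, stops NOT trimmed ('*' kept)."""
    return "".join(CODON_TABLE.get(nt[i:i + 3], "X")
                   for i in range(0, len(nt) - len(nt) % 3, 3))


def revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def read_fasta(path):
    seqs, name, parts = {}, None, []
    for line in open(path):
        line = line.strip()
        if line.startswith(">"):
            if name:
                seqs[name] = "".join(parts)
            name, parts = line[1:].split()[0], []
        elif line:
            parts.append(line)
    if name:
        seqs[name] = "".join(parts)
    return seqs
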