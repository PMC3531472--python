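"""Independent brute-force oracles used by the unit and acceptance suites.

Each oracle re-derives an operation's expected output from first
principles along a different code path than the implementation under
test: the SSR oracle enumerates every (start, unit-size) pair; the NG86
oracle enumerates mutational pathways directly from the genetic code;
the posterior oracle evaluates the 16 allele-pair likelihoods in plain
(non-log) arithmetic.
"""

import itertools
import math

from Bio.Data.CodonTable import standard_dna_table

MIN_UNITS = {2: 6, 3: 5, 4: 4, 5: 3, 6: 3}


def oracle_find_ssrs(seq):
    """Enumerate every (start, k): a locus is a qualifying leading
    complete-unit run of a maximal period-k region; then greedily keep
    longer tracts first (ties: smaller unit, leftmost), dropping
    overlaps. Returns (start, end, motif, unit_count) 1-based tuples."""
    n = len(seq)
    raw = []
    for k in range(2, 7):
        for i in range(n - k * MIN_UNITS[k] + 1):
            motif = seq[i : i + k]
            if set(motif) - set("ACGT"):
                continue
            if any(k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)):
                continue  # non-primitive
            # region must start here: the period predicate fails just before
            if i >= 1 and i - 1 + k < n and seq[i - 1] == seq[i - 1 + k] and seq[i - 1] in "ACGT":
                continue
            j = i + k
            while j < n and seq[j] in "ACGT" and seq[j] == seq[j - k]:
                j += 1
            units = (j - i) // k
            if units >= MIN_UNITS[k]:
                raw.append((i + 1, i + units * k, motif, units))
    kept = []
    for locus in sorted(raw, key=lambda t: (-(t[1] - t[0] + 1), len(t[2]), t[0], t[2])):
        if all(locus[1] < o[0] or o[1] < locus[0] for o in kept):
            kept.append(locus)
    return sorted(kept)


_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


def oracle_ng86(codon_pairs):
    """NG86 counts via direct enumeration: per-codon synonymous-site
    fractions from the genetic code, pathway averaging with stop
    exclusion, Jukes-Cantor correction. Returns (S, N, Sd, Nd, Ks, Ka)."""
    S = Sd = Nd = 0.0
    for ca, cb in codon_pairs:
        for codon in (ca, cb):
            syn = 0
            for pos in range(3):
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    alt = codon[:pos] + b + codon[pos + 1 :]
                    if alt not in _STOPS and _CODON_TO_AA[alt] == _CODON_TO_AA[codon]:
                        syn += 1
            S += syn / 3.0 / 2.0
        diffs = [i for i in range(3) if ca[i] != cb[i]]
        if not diffs:
            continue
        paths = []
        for order in itertools.permutations(diffs):
            steps = []
            cur = ca
            blocked = False
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in _STOPS:
                    blocked = True
                steps.append((cur, nxt))
                cur = nxt
            paths.append((blocked, steps))
        usable = [p for p in paths if not p[0]] or paths
        sd = nd = 0.0
        for _, steps in usable:
            for cur, nxt in steps:
                if (
                    cur not in _STOPS
                    and nxt not in _STOPS
                    and _CODON_TO_AA[cur] == _CODON_TO_AA[nxt]
                ):
                    sd += 1
                else:
                    nd += 1
        Sd += sd / len(usable)
        Nd += nd / len(usable)
    N = 3.0 * len(codon_pairs) - S
    ps, pn = Sd / S, Nd / N

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return S, N, Sd, Nd, jc(ps), jc(pn)


def oracle_site_posterior(bases_a, quals_a, bases_b, quals_b):
    """Posterior of a fixed difference by direct 16-pair evaluation."""

    def lik(bases, quals, x):
        p = 1.0
        for b, q in zip(bases, quals):
            e = min(10.0 ** (-q / 10.0), 0.75)
            p *= (1 - e) if b == x else e / 3.0
        return p

    table = {
        (xa, xb): lik(bases_a, quals_a, xa) * lik(bases_b, quals_b, xb)
        for xa in "ACGT"
        for xb in "ACGT"
    }
    total = sum(table.values())
    return sum(v for (xa, xb), v in table.items() if xa != xb) / total
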