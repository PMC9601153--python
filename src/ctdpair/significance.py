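"""Closed-form significance machinery for shared node modules.

A module S proposed from graph G1 and tested in graph G2 is scored by the
weighted-Bonferroni-corrected bound

    log2 p  <=  I_A(G1) + I_A(G2) - I_0(G2),

where I_A are the alternate (diffusion-compressed) encoding lengths of S in
each graph and I_0(G2) = |S| * log2(|V2|) is the null encoding length.  The
Bonferroni weight for S is its probability under the encoding-induced
distribution on the power set of G1, bounded conservatively by 2^(-I_A(G1));
the per-graph p-value in G2 comes from the algorithmic significance theorem,
p <= 2^-(I_0 - I_A).  Both bounds multiply into the expression above.

Two closed forms describe the best case (every module node captured, no
stray visits): an ideal p-value bound 4*(4/|V|)^(|S|-2), and its inversion,
the smallest module size that can reach a wanted significance level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .encoder import Encoding

__all__ = [
    "SignificanceResult",
    "null_encoding_length",
    "pair_bound",
    "ideal_bound",
    "min_module_size",
    "subset_log2_probability",
    "ideal_encoding",
]

#: thresholds pre-evaluated on every result; the raw bound is always kept too
DEFAULT_THRESHOLDS = (0.05, 1e-3, 5e-10)


@dataclass(frozen=True)
class SignificanceResult:
    """Outcome of bounding the p-value of one module on one graph pair.

    ``p_bound`` may exceed 1; it is a bound, not a probability estimate, and
    values above 1 simply read "not significant".
    """

    i_alt_g1: float
    i_alt_g2: float
    i_null_g2: float
    log2_p_bound: float
    p_bound: float
    significant_at: dict[float, bool] = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "I_A_g1": self.i_alt_g1,
            "I_A_g2": self.i_alt_g2,
            "I_0_g2": self.i_null_g2,
            "log2_p_bound": round(self.log2_p_bound, 4),
            "p_bound": self.p_bound,
            "significant_at": {str(t): v for t, v in self.significant_at.items()},
        }


def null_encoding_length(n_nodes: int, module_size: int) -> float:
    """Null-hypothesis code length I_0 = |S| * log2(|V|), in bits.

    Valid only while the module is small relative to the graph,
    |S| < 2|V|/log2(|V|); beyond that the per-node log2|V| accounting of the
    null model breaks down and an error is raised.
    """
    if n_nodes < 2:
        raise ValueError("null model needs at least 2 nodes")
    if module_size < 1:
        raise ValueError("module size must be positive")
    if not module_size < 2 * n_nodes / math.log2(n_nodes):
        raise ValueError("module too large for null-model formula")
    return module_size * math.log2(n_nodes)


def pair_bound(
    enc1: Encoding,
    enc2: Encoding,
    n2: int | None = None,
    module_size: int | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> SignificanceResult:
    """Weighted-Bonferroni p-value bound for a module encoded in both graphs.

    ``enc1`` is the proposer-side encoding (supplies the Bonferroni weight),
    ``enc2`` the tester-side one; the null length uses the tester's node count
    only.  ``n2`` and ``module_size`` default to the tester encoding's own
    bookkeeping.
    """
    if enc1.module_size != enc2.module_size:
        raise ValueError(
            f"encodings refer to different module sizes "
            f"({enc1.module_size} vs {enc2.module_size})"
        )
    if module_size is None:
        module_size = enc2.module_size
    if module_size != enc2.module_size:
        raise ValueError("module_size does not match the tester encoding")
    if n2 is None:
        n2 = enc2.n_nodes
    i_null = null_encoding_length(n2, module_size)
    log2_p = enc1.i_alt + enc2.i_alt - i_null
    p = 2.0**log2_p
    return SignificanceResult(
        i_alt_g1=enc1.i_alt,
        i_alt_g2=enc2.i_alt,
        i_null_g2=i_null,
        log2_p_bound=log2_p,
        p_bound=p,
        significant_at={t: p < t for t in thresholds},
    )


def ideal_bound(n_nodes: int, module_size: int) -> float:
    """Best-case p-value bound 4*(4/|V|)^(|S|-2) for a perfectly captured module.

    This is the pair bound evaluated at the ideal encodings
    I_A = log2|V| + |S| - 1 in both graphs.  A warning is emitted when the
    module is large enough that the null-model smallness assumption
    (|S| < 2|V|/log2|V|) no longer strictly holds; the closed form is still
    returned since it remains the algebraic best case.
    """
    if n_nodes <= 4:
        raise ValueError("bound undefined for graphs of 4 or fewer nodes")
    if module_size < 2:
        raise ValueError("ideal bound requires a module of at least 2 nodes")
    if not module_size < 2 * n_nodes / math.log2(n_nodes):
        warnings.warn(
            "module size violates the smallness assumption of the null model; "
            "the ideal bound is extrapolated",
            RuntimeWarning,
            stacklevel=2,
        )
    return 4.0 * (4.0 / n_nodes) ** (module_size - 2)


def min_module_size(n_nodes: int, p_wanted: float) -> int:
    """Smallest module size whose ideal-case bound can reach ``p_wanted``.

    Inverts the ideal bound: |S| >= 2 + (2 - log2 p) / (log2|V| - 2), rounded
    up ("at least" semantics; an exactly integral right-hand side is returned
    as-is).  Note this is a detectability floor, not a guarantee: a module of
    this size still needs near-ideal connectedness in both graphs to reach
    the wanted level.
    """
    if n_nodes <= 4:
        raise ValueError("bound undefined: need log2(|V|) > 2, i.e. |V| > 4")
    if not 0.0 < p_wanted <= 1.0:
        raise ValueError("p_wanted must lie in (0, 1]")
    rhs = 2.0 + (2.0 - math.log2(p_wanted)) / (math.log2(n_nodes) - 2.0)
    return math.ceil(rhs)


def subset_log2_probability(enc: Encoding) -> float:
    """log2 of the conservative occurrence probability of the encoded subset.

    The encoding-induced distribution on the power set gives
    P(A) = 2^(-l(A))/k >= 2^(-l(A)); the normalizer k is never computed, so
    -I_A is the usable log2 lower bound.  This is the weighted-Bonferroni
    weight w_A of the subset.
    """
    return -enc.i_alt


def ideal_encoding(n_nodes: int, module_size: int, start: str = "s") -> Encoding:
    """Synthetic best-case encoding: all of S captured with no stray visits.

    Bitstring of |S| ones, so I_A = log2|V| + |S| - 1.  Useful for closed-form
    cross-checks; not tied to any actual graph.
    """
    return Encoding(
        start=start, bits="1" * module_size, module_size=module_size, n_nodes=n_nodes
    )
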