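"""Integer Laurent polynomials in the Kauffman bracket variable A.

The Jones polynomial of a knot is a Laurent polynomial in t = A**-4; for
links with an even number of components half-integer powers of t appear,
which is why the bracket variable A (where every exponent is an integer)
is used as the internal representation throughout.
"""

from __future__ import annotations

from fractions import Fraction


class Laurent:
    """Sparse integer Laurent polynomial in one variable (A)."""

    __slots__ = ("coeffs",)

    def __init__(self, coeffs: dict[int, int] | None = None):
        self.coeffs = {e: c for e, c in (coeffs or {}).items() if c != 0}

    @classmethod
    def zero(cls) -> "Laurent":
        return cls({})

    @classmethod
    def one(cls) -> "Laurent":
        return cls({0: 1})

    @classmethod
    def monomial(cls, exponent: int, coeff: int = 1) -> "Laurent":
        return cls({exponent: coeff})

    def __bool__(self) -> bool:
        return bool(self.coeffs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Laurent):
            return NotImplemented
        return self.coeffs == other.coeffs

    def __hash__(self) -> int:
        return hash(self.key())

    def key(self) -> tuple[tuple[int, int], ...]:
        """Canonical hashable form."""
        return tuple(sorted(self.coeffs.items()))

    def __add__(self, other: "Laurent") -> "Laurent":
        out = dict(self.coeffs)
        for e, c in other.coeffs.items():
            out[e] = out.get(e, 0) + c
        return Laurent(out)

    def __neg__(self) -> "Laurent":
        return Laurent({e: -c for e, c in self.coeffs.items()})

    def __sub__(self, other: "Laurent") -> "Laurent":
        return self + (-other)

    def __mul__(self, other) -> "Laurent":
        if isinstance(other, int):
            return Laurent({e: c * other for e, c in self.coeffs.items()})
        out: dict[int, int] = {}
        for e1, c1 in self.coeffs.items():
            for e2, c2 in other.coeffs.items():
                e = e1 + e2
                out[e] = out.get(e, 0) + c1 * c2
        return Laurent(out)

    __rmul__ = __mul__

    def __pow__(self, n: int) -> "Laurent":
        if n < 0:
            # only unit monomials are invertible
            if len(self.coeffs) != 1:
                raise ValueError("negative power of a non-monomial")
            ((e, c),) = self.coeffs.items()
            if c not in (1, -1):
                raise ValueError("negative power needs a unit coefficient")
            return Laurent({e * n: c if n % 2 else 1})
        out = Laurent.one()
        base = self
        while n:
            if n & 1:
                out = out * base
            base = base * base
            n >>= 1
        return out

    def shifted(self, k: int) -> "Laurent":
        """Multiply by A**k."""
        return Laurent({e + k: c for e, c in self.coeffs.items()})

    def mirror(self) -> "Laurent":
        """A -> A**-1 (equivalently t -> 1/t on the Jones polynomial)."""
        return Laurent({-e: c for e, c in self.coeffs.items()})

    def __call__(self, a: float) -> float:
        """Evaluate at a real A != 0."""
        return sum(c * a**e for e, c in self.coeffs.items())

    def min_degree(self) -> int:
        return min(self.coeffs) if self.coeffs else 0

    def max_degree(self) -> int:
        return max(self.coeffs) if self.coeffs else 0

    def span_t(self) -> Fraction:
        """Degree span as a power of t = A**-4.

        For a reduced alternating diagram this equals the crossing number
        of the knot or link (the Kauffman–Murasugi–Thistlethwaite bound),
        which is used as a structural self-check on the shipped knot table.
        """
        if not self.coeffs:
            return Fraction(0)
        return Fraction(self.max_degree() - self.min_degree(), 4)

    def determinant(self) -> int:
        """|V(t = -1)| = |evaluation at A = exp(i pi / 4)| ... computed
        exactly: t = -1 corresponds to A**4 = -1, so evaluate the
        polynomial at A = primitive 8th root of unity using Gaussian
        integers over sqrt(2) arithmetic."""
        # A = e^{i pi/4}; A^k cycles with period 8:
        # k mod 8: 0:1, 1:(1+i)/s2, 2:i, 3:(-1+i)/s2, 4:-1, 5:-(1+i)/s2,
        # 6:-i, 7:(1-i)/s2   (s2 = sqrt 2)
        # Track value as (a + b*i + (c + d*i)/sqrt2); exponents here are
        # all even or all odd mod 2 per component-parity, so the result is
        # either purely in Z[i] or Z[i]/sqrt2.
        re_i = [ (1,0), (0,0), (0,1), (0,0), (-1,0), (0,0), (0,-1), (0,0) ]
        rt_i = [ (0,0), (1,1), (0,0), (-1,1), (0,0), (-1,-1), (0,0), (1,-1) ]
        a = b = c = d = 0
        for e, coef in self.coeffs.items():
            k = e % 8
            a += coef * re_i[k][0]
            b += coef * re_i[k][1]
            c += coef * rt_i[k][0]
            d += coef * rt_i[k][1]
        # |z|^2 where z = a+bi + (c+di)/sqrt2
        val = (a * a + b * b) + (c * c + d * d) / 2.0 + 2 ** 0.5 * (a * c + b * d)
        return round(val ** 0.5)

    def t_string(self) -> str:
        """Render as a polynomial in t = A**-4 (half/quarter powers allowed)."""
        if not self.coeffs:
            return "0"
        terms = []
        for e in sorted(self.coeffs, reverse=True):  # descending A = ascending t
            c = self.coeffs[e]
            p = Fraction(-e, 4)
            if p == 0:
                terms.append(f"{c:+d}")
            else:
                pe = f"t^{p}" if p.denominator > 1 or p != 1 else "t"
                if p.denominator == 1 and p == 1:
                    pe = "t"
                elif p.denominator == 1:
                    pe = f"t^{p.numerator}"
                if c == 1:
                    terms.append(f"+{pe}")
                elif c == -1:
                    terms.append(f"-{pe}")
                else:
                    terms.append(f"{c:+d}*{pe}")
        s = " ".join(terms)
        return s[1:] if s.startswith("+") else s

    def __repr__(self) -> str:  # pragma: no cover
        return f"Laurent({self.t_string()} [t])"
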