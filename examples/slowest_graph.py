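"""The slowest structure to colonize: the backward graph.

Builds backward graphs B_n (a one-way path left to right plus every
one-way edge going right to left), solves the expected colonization time
exactly from the path start, and compares it with the general cubic bound
n^3/2 - n^2/2 — which the backward graph attains with equality.
"""

from fractions import Fraction

from morancol import backward_graph, colonization_exact

print(f"{'n':>4} {'T(B_n, 0)':>12} {'n^3/2 - n^2/2':>14}  tight?")
for n in (4, 8, 16, 24, 32):
    res = colonization_exact(backward_graph(n), {0}, arithmetic="rational")
    bound = Fraction(n**3 - n**2, 2)
    t = res.expected_modified_steps
    print(f"{n:>4} {str(t):>12} {str(bound):>14}  {t == bound}")

# Every row prints True: for each population size the backward graph is
# exactly as slow as any structure can possibly be.
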