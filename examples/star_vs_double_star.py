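"""Undirected structures: the star outpaces the double star — slowly.

Among undirected graphs the star S_n is the slowest structure found for
colonization (time n(n-1)H(n-1), of order n^2 log n), and it is a constant
factor slower than the double star D_n at the same population size n —
the reverse of the finite-fitness regime, where the double star is the
slow one.  Both sit far below the proved undirected bound 4 n^2 sqrt(n).
"""

from morancol import closed_form, double_star_exact

print(f"{'n':>5} {'T(star)':>12} {'T(double star)':>15} {'ratio':>6} {'bound':>12}")
for n in (40, 100, 200):
    t_star = closed_form("star", n)
    t_ds = double_star_exact(n // 2).second.expected_modified_steps  # leaf start
    bound = 4 * n**2 * n**0.5
    print(f"{n:>5} {t_star:>12.1f} {t_ds:>15.1f} {t_star / t_ds:>6.2f} {bound:>12.0f}")

# The ratio settles near 1.7-1.8: a constant factor, not a different
# growth order — both families scale as n^2 log n.
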