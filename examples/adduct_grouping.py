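"""Group co-eluting MS1 ions into a neutral-mass hypothesis.

Five measured features — two singly and three doubly charged — are tested
against the standard positive-mode adduct set.  They collapse onto a
single neutral mass, which is how an unknown's intact mass is established
before any fragmentation work.
"""

from nodmet import group_adducts

measured = [
    (1022.0960, 2),
    (1033.0848, 2),
    (1044.0746, 2),
    (2043.1830, 1),
    (2065.1664, 1),
]

for hyp in group_adducts(measured, tol_ppm=5.0):
    print(f"neutral mass {hyp.neutral_mass:.4f} Da "
          f"(mean |error| {hyp.score:.2f} ppm)")
    for mz, adduct, ppm in sorted(hyp.supporters):
        print(f"  m/z {mz:>9.4f}  as {adduct.name:<12} ({ppm:+.2f} ppm)")

# All five ions support one molecule near 2042.175 Da: the mass of
# britacidin A.  An ion left unexplained here would instead suggest a
# co-eluting second compound.
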