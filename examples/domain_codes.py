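"""Compare NRPS adenylation-domain specificity codes between two clusters.

Aligns a 17-module query cluster against a 15-module gramicidin-type
reference using Stachelhaus-code identity, reporting inserted modules and
nearest-neighbour substrate predictions.  The bundled code tables are
synthetic stand-ins consistent with the britacidin/gramicidin module
architecture (see the fixture header).
"""

from nodmet.stachelhaus import (
    map_domains,
    predict_substrate,
    read_code_table,
    reference_from_cluster,
    synthetic_codes_path,
)

path = synthetic_codes_path()
clusters, _ = read_code_table(path)
reference = reference_from_cluster(path, "ref")

aln = map_domains(clusters["bri"], clusters["lgr"], gap_penalty=0.4)
print(f"alignment score {aln.score:.1f}; "
      f"inserted query modules: {aln.insertions}")

print("module  aligned-to  predicted substrate (identity)")
by_index = {c.module_index: c for c in clusters["bri"]}
for qi, rj in aln.pairs:
    subs, ident = predict_substrate(by_index[qi].code, reference, 0.8)
    call = "/".join(subs) if subs else "no-call"
    ref_str = f"lgr m{rj}" if rj else "— (insertion)"
    print(f"  m{qi:<4}  {ref_str:<12} {call} ({ident:.1f})")

# The two inserted modules at chemical positions 7 and 8 predict Ala and
# Val — the residues that extend the britacidin backbone relative to
# gramicidin — and the position-11 module predicts Tyr where gramicidins
# carry Trp.
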