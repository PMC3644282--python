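# Boolean model of the cholesterol regulatory pathway, version 1.
# Topology reduced from the boolean cholesterol-biosynthesis model of
# Kervizic & Corcos (BMC Systems Biology 2008): the synthesis chain from the
# precursor Acetyl-CoA through HMG-CoA, mevalonic acid and the isoprenoid /
# sterol intermediates to cholesterol; the SREBP-SCAP transcriptional program
# (cholesterol represses it) driving the synthesis enzymes; and statins
# inhibition of HMG-CoA reductase. Every multi-input node is AND logic except
# Cholesterol, whose two final synthesis branches (desmosterol and
# 7-dehydrocholesterol) combine with OR.
# Statins and Acetyl_CoA are inputs: they hold their state unless clamped.
Statins = Statins
Acetyl_CoA = Acetyl_CoA
SREBP_SCAP = NOT Cholesterol
HMG_CoA_synthase = SREBP_SCAP
HMG_CoA = Acetyl_CoA AND HMG_CoA_synthase
HMG_CoA_reductase = SREBP_SCAP AND NOT Statins
Mevalonic_acid = HMG_CoA AND HMG_CoA_reductase
Mevalonate_kinase = SREBP_SCAP
Isopentenyl_PP = Mevalonic_acid AND Mevalonate_kinase
FPP_synthase = SREBP_SCAP
Geranyl_PP = Isopentenyl_PP AND FPP_synthase
Farnesyl_PP = Geranyl_PP AND FPP_synthase
Squalene_synthase = SREBP_SCAP
Squalene = Farnesyl_PP AND Squalene_synthase
Lanosterol = Squalene
Desmosterol = Lanosterol
Dehydrocholesterol_7 = Lanosterol
Cholesterol = Desmosterol OR Dehydrocholesterol_7
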