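# SYNTHETIC stand-in dating table (not measured data).
# Per-species ortholog Ks peaks against L. barbarum with divergence times,
# constructed to be consistent with a WGT Ks peak of 0.65, per-lineage rate
# calibration lambda = ks_peak / time_mya, WGT ages spanning 64.83-75.54 Mya
# (mean 69), and all events younger than the 82.8 Mya Solanaceae-Rubiaceae split.
species	ks_peak	time_mya
S.lycopersicum	0.45	44.8823
N.tabacum	0.52	53.4320
P.axillaris	0.58	61.4266
I.nil	0.70	81.3508
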