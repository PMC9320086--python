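# SYNTHETIC per-patient mean-SDI scores (two clinical groups).  These are
# constructed values, not patient data: they reproduce the published group
# summary statistics (svPPA mean 3.99, SD 0.32; lvPPA mean 4.42, SD 0.37;
# Mann-Whitney U = 19.0, exact two-sided p = 0.033) but the individual
# numbers are an invention of the generator that produced this file.
group	speaker	mean_sdi
svPPA	sv01	3.63
svPPA	sv02	3.84
svPPA	sv03	3.85
svPPA	sv04	3.89
svPPA	sv05	4.25
svPPA	sv06	4.50
lvPPA	lv01	3.57
lvPPA	lv02	3.82
lvPPA	lv03	4.04
lvPPA	lv04	4.18
lvPPA	lv05	4.27
lvPPA	lv06	4.33
lvPPA	lv07	4.46
lvPPA	lv08	4.49
lvPPA	lv09	4.52
lvPPA	lv10	4.53
lvPPA	lv11	4.54
lvPPA	lv12	4.62
lvPPA	lv13	4.68
lvPPA	lv14	4.79
lvPPA	lv15	4.91
lvPPA	lv16	4.92
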