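m_squared,dm2_dtau
0.02,-0.534020
0.06,-0.522380
0.10,-0.511700
0.14,-0.501980
0.18,-0.493220
0.22,-0.485420
0.26,-0.478580
0.30,-0.472700
0.34,-0.467780
0.38,-0.463820
0.42,-0.460820
0.46,-0.458780
0.50,-0.457700
0.54,-0.457580
0.58,-0.458420
0.62,-0.460220
0.66,-0.462980
0.70,-0.466700
0.74,-0.471380
0.78,-0.477020
0.82,-0.483620
0.86,-0.491180
0.90,-0.499700
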