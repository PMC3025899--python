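population	coordinate	elevation_m
SZS	106°49'E 39°25'N	1130
HN	106°54'E 39°33'N	1280
GLS	106°50'E 39°50'N	1170
XD	106°46'E 39°52'N	1090
YKBLG	106°49'E 40°05'N	1070
TST	106°54'E 40°09'N	1070
MSG	107°04'E 40°07'N	1380
BLG	107°03'E 40°16'N	1100
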