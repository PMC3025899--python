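clade	level	members
1-1	1	H34,H35,H36,H37
1-2	1	H01,H02,H38
1-3	1	H03,H04,H05,H06,H07,H08
1-4	1	H09,H10,H11,H12,H13
1-5	1	H14,H15,H16,H17,H18,H19
1-6	1	H30,H31,H32,H33
1-7	1	H24,H25,H26,H27,H28,H29
1-8	1	H20,H21,H22,H23
2-1	2	1-1,1-2
2-2	2	1-3
2-3	2	1-4,1-5
2-4	2	1-6,1-7
2-5	2	1-8
3-1	3	2-1,2-2
3-2	3	2-3,2-4,2-5
total	4	3-1,3-2
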