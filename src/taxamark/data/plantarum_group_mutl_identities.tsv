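# Published pairwise percent identities of mutL sequences among the 17
# type strains of the Lactiplantibacillus plantarum species group.
label	species	Lplantarum_BCRC10069T	Largentoratensis_BCRC17638T	Lparaplantarum_BCRC17178T	Lpentosus_BCRC11053T	Ldaoliensis_116-1AT	Lpingfangensis_382-1T	Ldaowaiensis_203-3T	Lgarii_FI11369T	Lnangangensis_381-7T	Lherbarum_BCRC80996T	Lfabifermentans_BCRC18841T	Lplajomi_BCRC80928T	Lxiangfangensis_BCRC80512T	Lmodestisalitolerans_BCRC80927T	Ldongliensis_218-3T	Lsongbeiensis_398-2T	Lmudanjiangensis_11050T
Lplantarum_BCRC10069T	L. plantarum	100.0	85.6	76.1	69.4	64.9	64.0	64.5	67.0	64.8	67.9	64.6	65.9	68.1	66.8	65.0	65.7	64.9
Largentoratensis_BCRC17638T	L. argentoratensis	85.6	100.0	73.6	68.6	65.1	64.4	64.6	66.2	65.4	66.6	64.7	65.6	68.0	66.4	63.8	65.1	64.4
Lparaplantarum_BCRC17178T	L. paraplantarum	76.1	73.6	100.0	69.3	66.7	66.2	66.5	66.4	66.5	68.1	66.2	65.4	68.8	65.2	67.0	66.1	66.6
Lpentosus_BCRC11053T	L. pentosus	69.4	68.6	69.3	100.0	65.4	65.9	66.5	66.5	63.3	66.4	64.1	65.8	67.9	64.5	65.8	67.5	66.1
Ldaoliensis_116-1AT	L. daoliensis	64.9	65.1	66.7	65.4	100.0	71.6	65.6	65.9	73.8	63.7	66.4	64.5	64.3	65.1	66.0	66.3	65.9
Lpingfangensis_382-1T	L. pingfangensis	64.0	64.4	66.2	65.9	71.6	100.0	70.4	64.5	73.0	66.3	65.9	65.5	66.5	66.2	65.8	66.9	69.9
Ldaowaiensis_203-3T	L. daowaiensis	64.5	64.6	66.5	66.5	65.6	70.4	100.0	66.0	66.1	64.3	68.2	62.7	66.1	67.0	70.2	69.5	71.1
Lgarii_FI11369T	L. garii	67.0	66.2	66.4	66.5	65.9	64.5	66.0	100.0	61.6	64.9	65.4	69.6	73.3	64.6	66.1	66.3	64.3
Lnangangensis_381-7T	L. nangangensis	64.8	65.4	66.5	63.3	73.8	73.0	66.1	61.6	100.0	63.8	66.7	63.4	65.4	64.3	66.0	67.6	67.6
Lherbarum_BCRC80996T	L. herbarum	67.9	66.6	68.1	66.4	63.7	66.3	64.3	64.9	63.8	100.0	64.0	64.9	67.7	62.4	64.0	64.6	64.3
Lfabifermentans_BCRC18841T	L. fabifermentans	64.6	64.7	66.2	64.1	66.4	65.9	68.2	65.4	66.7	64.0	100.0	62.7	64.5	65.0	66.3	67.3	66.1
Lplajomi_BCRC80928T	L. plajomi	65.9	65.6	65.4	65.8	64.5	65.5	62.7	69.6	63.4	64.9	62.7	100.0	68.1	64.3	65.4	64.8	62.8
Lxiangfangensis_BCRC80512T	L. xiangfangensis	68.1	68.0	68.8	67.9	64.3	66.5	66.1	73.3	65.4	67.7	64.5	68.1	100.0	65.6	68.0	70.5	68.6
Lmodestisalitolerans_BCRC80927T	L. modestisalitolerans	66.8	66.4	65.2	64.5	65.1	66.2	67.0	64.6	64.3	62.4	65.0	64.3	65.6	100.0	67.0	67.7	66.0
Ldongliensis_218-3T	L. dongliensis	65.0	63.8	67.0	65.8	66.0	65.8	70.2	66.1	66.0	64.0	66.3	65.4	68.0	67.0	100.0	80.2	69.9
Lsongbeiensis_398-2T	L. songbeiensis	65.7	65.1	66.1	67.5	66.3	66.9	69.5	66.3	67.6	64.6	67.3	64.8	70.5	67.7	80.2	100.0	70.3
Lmudanjiangensis_11050T	L. mudanjiangensis	64.9	64.4	66.6	66.1	65.9	69.9	71.1	64.3	67.6	64.3	66.1	62.8	68.6	66.0	69.9	70.3	100.0
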