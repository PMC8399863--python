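# Published pairwise percent identities of 16S rRNA sequences among the 17
# type strains of the Lactiplantibacillus plantarum species group.
label	species	Lplantarum_BCRC10069T	Largentoratensis_BCRC17638T	Lparaplantarum_BCRC17178T	Lpentosus_BCRC11053T	Ldaoliensis_116-1AT	Lpingfangensis_382-1T	Ldaowaiensis_203-3T	Lgarii_FI11369T	Lnangangensis_381-7T	Lherbarum_BCRC80996T	Lfabifermentans_BCRC18841T	Lplajomi_BCRC80928T	Lxiangfangensis_BCRC80512T	Lmodestisalitolerans_BCRC80927T	Ldongliensis_218-3T	Lsongbeiensis_398-2T	Lmudanjiangensis_11050T
Lplantarum_BCRC10069T	L. plantarum	100.0	100.0	99.7	99.9	99.0	99.0	98.9	98.9	98.9	98.9	98.9	98.8	98.7	98.5	98.0	97.9	97.8
Largentoratensis_BCRC17638T	L. argentoratensis	100.0	100.0	99.7	99.9	99.0	99.0	98.9	98.9	98.9	98.9	98.9	98.8	98.7	98.5	98.0	97.9	97.8
Lparaplantarum_BCRC17178T	L. paraplantarum	99.7	99.7	100.0	99.8	99.0	99.2	98.8	98.9	99.0	98.9	98.9	98.5	98.7	98.4	97.8	97.9	97.9
Lpentosus_BCRC11053T	L. pentosus	99.9	99.9	99.8	100.0	99.1	99.1	98.9	98.9	99.0	98.9	98.9	98.7	98.8	98.5	97.9	98.0	97.9
Ldaoliensis_116-1AT	L. daoliensis	99.0	99.0	99.0	99.1	100.0	99.7	98.5	98.5	99.9	98.3	98.5	98.0	99.0	97.8	97.9	98.1	97.9
Lpingfangensis_382-1T	L. pingfangensis	99.0	99.0	99.2	99.1	99.7	100.0	98.5	98.5	99.8	98.5	98.6	97.8	99.0	97.7	98.1	98.2	98.1
Ldaowaiensis_203-3T	L. daowaiensis	98.9	98.9	98.8	98.9	98.5	98.5	100.0	98.7	98.6	98.0	98.5	98.2	98.4	97.8	98.3	98.2	98.5
Lgarii_FI11369T	L. garii	98.9	98.9	98.9	98.9	98.5	98.5	98.7	100.0	98.6	98.0	98.5	99.0	99.4	98.7	97.6	97.5	97.6
Lnangangensis_381-7T	L. nangangensis	98.9	98.9	99.0	99.0	99.9	99.8	98.6	98.6	100.0	98.4	98.5	97.9	99.1	97.8	98.0	98.2	98.0
Lherbarum_BCRC80996T	L. herbarum	98.9	98.9	98.9	98.9	98.3	98.5	98.0	98.0	98.4	100.0	98.3	97.7	98.0	97.5	97.3	97.4	97.6
Lfabifermentans_BCRC18841T	L. fabifermentans	98.9	98.9	98.9	98.9	98.5	98.6	98.5	98.5	98.5	98.3	100.0	98.1	98.5	97.5	97.5	97.6	97.5
Lplajomi_BCRC80928T	L. plajomi	98.8	98.8	98.5	98.7	98.0	97.8	98.2	99.0	97.9	97.7	98.1	100.0	98.7	98.9	96.9	96.9	96.9
Lxiangfangensis_BCRC80512T	L. xiangfangensis	98.7	98.7	98.7	98.8	99.0	99.0	98.4	99.4	99.1	98.0	98.5	98.7	100.0	98.4	97.9	98.0	97.5
Lmodestisalitolerans_BCRC80927T	L. modestisalitolerans	98.5	98.5	98.4	98.5	97.8	97.7	97.8	98.7	97.8	97.5	97.5	98.9	98.4	100.0	96.8	96.7	96.8
Ldongliensis_218-3T	L. dongliensis	98.0	98.0	97.8	97.9	97.9	98.1	98.3	97.6	98.0	97.3	97.5	96.9	97.9	96.8	100.0	99.8	98.7
Lsongbeiensis_398-2T	L. songbeiensis	97.9	97.9	97.9	98.0	98.1	98.2	98.2	97.5	98.2	97.4	97.6	96.9	98.0	96.7	99.8	100.0	98.8
Lmudanjiangensis_11050T	L. mudanjiangensis	97.8	97.8	97.9	97.9	97.9	98.1	98.5	97.6	98.0	97.6	97.5	96.9	97.5	96.8	98.7	98.8	100.0
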