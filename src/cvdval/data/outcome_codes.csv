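model_id,code_system,code,role
SCORE,ICD-10,I20,fatal
SCORE,ICD-10,I21,fatal
SCORE,ICD-10,I22,fatal
SCORE,ICD-10,I23,fatal
SCORE,ICD-10,I24,fatal
SCORE,ICD-10,I25,fatal
SCORE,ICD-10,I60,fatal
SCORE,ICD-10,I61,fatal
SCORE,ICD-10,I62,fatal
SCORE,ICD-10,I63,fatal
SCORE,ICD-10,I64,fatal
SCORE,ICD-10,I65,fatal
SCORE,ICD-10,I66,fatal
SCORE,ICD-10,I70,fatal
SCORE,ICD-10,I71,fatal
SCORE,ICD-10,I72,fatal
SCORE,ICD-10,I73,fatal
SCORE,ICD-10,I74,fatal
SCORE_FNF,ICD-10,I20,fatal
SCORE_FNF,ICD-10,I21,fatal
SCORE_FNF,ICD-10,I22,fatal
SCORE_FNF,ICD-10,I23,fatal
SCORE_FNF,ICD-10,I24,fatal
SCORE_FNF,ICD-10,I25,fatal
SCORE_FNF,ICD-10,I60,fatal
SCORE_FNF,ICD-10,I61,fatal
SCORE_FNF,ICD-10,I62,fatal
SCORE_FNF,ICD-10,I63,fatal
SCORE_FNF,ICD-10,I64,fatal
SCORE_FNF,ICD-10,I65,fatal
SCORE_FNF,ICD-10,I66,fatal
SCORE_FNF,ICD-10,I70,fatal
SCORE_FNF,ICD-10,I71,fatal
SCORE_FNF,ICD-10,I72,fatal
SCORE_FNF,ICD-10,I73,fatal
SCORE_FNF,ICD-10,I74,fatal
SCORE_FNF,ICPC,K75,nonfatal
SCORE_FNF,ICPC,K77,nonfatal
SCORE_FNF,ICPC,K90,nonfatal
SCORE_FNF,ICPC,K92,nonfatal
GLOBO_LAB,ICD-10,I20,fatal
GLOBO_LAB,ICD-10,I21,fatal
GLOBO_LAB,ICD-10,I22,fatal
GLOBO_LAB,ICD-10,I23,fatal
GLOBO_LAB,ICD-10,I24,fatal
GLOBO_LAB,ICD-10,I25,fatal
GLOBO_LAB,ICD-10,I60,fatal
GLOBO_LAB,ICD-10,I61,fatal
GLOBO_LAB,ICD-10,I62,fatal
GLOBO_LAB,ICD-10,I63,fatal
GLOBO_LAB,ICD-10,I64,fatal
GLOBO_LAB,ICD-10,I46,fatal
GLOBO_LAB,ICPC,K75,nonfatal
GLOBO_LAB,ICPC,K90,nonfatal
GLOBO_OFFICE,ICD-10,I20,fatal
GLOBO_OFFICE,ICD-10,I21,fatal
GLOBO_OFFICE,ICD-10,I22,fatal
GLOBO_OFFICE,ICD-10,I23,fatal
GLOBO_OFFICE,ICD-10,I24,fatal
GLOBO_OFFICE,ICD-10,I25,fatal
GLOBO_OFFICE,ICD-10,I60,fatal
GLOBO_OFFICE,ICD-10,I61,fatal
GLOBO_OFFICE,ICD-10,I62,fatal
GLOBO_OFFICE,ICD-10,I63,fatal
GLOBO_OFFICE,ICD-10,I64,fatal
GLOBO_OFFICE,ICD-10,I46,fatal
GLOBO_OFFICE,ICPC,K75,nonfatal
GLOBO_OFFICE,ICPC,K90,nonfatal
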