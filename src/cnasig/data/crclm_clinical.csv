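patient_id,sex,age,synchronous,relapse,multifocal,cea_elevated,ln_count,stage,primary_site,rfs_time,rfs_event,os_time,os_event
CRCLM-01,F,73,Yes,Relapse,No,Yes,3,IVA,transverse,,,,
CRCLM-02,M,43,No,Relapse,No,No,2,IIIB,rectum,,,,
CRCLM-03,M,50,Yes,Relapse,No,No,1,IVA,descending,,,,
CRCLM-04,M,83,Yes,No,Yes,Yes,0,IVA,rectosigmoid,,,,
CRCLM-05,M,71,No,No,No,No,1,IIIB,cecum,,,,
CRCLM-06,M,69,No,Relapse,No,No,0,IIA,rectum,,,,
CRCLM-07,F,69,Yes,Relapse,Yes,No,12,IVA,transverse,,,,
CRCLM-08,M,67,Yes,Relapse,Yes,Yes,7,IVA,rectum,,,,
CRCLM-09,F,60,Yes,No,Yes,Yes,0,IVA,ascending,,,,
CRCLM-10,M,61,No,No,Yes,Yes,7,IIIC,rectum,,,,
CRCLM-11,F,45,Yes,Relapse,Yes,Yes,4,IVA,sigmoid,,,,
CRCLM-12,F,70,Yes,No,Yes,Yes,7,IVA,rectosigmoid,,,,
CRCLM-13,F,57,Yes,Relapse,No,Yes,5,IVA,ascending,,,,
CRCLM-14,M,66,Yes,No,Yes,Yes,0,IVA,sigmoid,,,,
CRCLM-15,M,46,No,No,Yes,No,0,IIA,rectum,,,,
CRCLM-17,F,47,Yes,No,No,No,4,IVA,rectum,,,,
CRCLM-18,F,39,Yes,Relapse,No,No,1,IVA,rectum,,,,
CRCLM-19,M,58,Yes,Relapse,No,Yes,15,IVA,rectum,,,,
CRCLM-20,M,73,No,Relapse,No,No,0,IIA,ascending,,,,
CRCLM-22,M,63,No,Relapse,No,No,3,IIIB,rectum,,,,
CRCLM-23,F,69,No,Relapse,No,Yes,3,IIIB,sigmoid,,,,
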