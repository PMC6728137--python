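gene,segment,cdr3_germline
TCRBV01-01,V,CTSS
TCRBV02-01,V,CASS
TCRBV03-01,V,CASS
TCRBV04-01,V,CASS
TCRBV04-02,V,CASS
TCRBV04-03,V,CASS
TCRBV05-01,V,CASS
TCRBV05-02,V,CASS
TCRBV05-03,V,CASS
TCRBV05-04,V,CASS
TCRBV05-05,V,CASS
TCRBV05-06,V,CASS
TCRBV05-07,V,CASS
TCRBV05-08,V,CASS
TCRBV05-09,V,CASS
TCRBV06-01,V,CASS
TCRBV06-02,V,CASS
TCRBV06-03,V,CASS
TCRBV06-04,V,CASS
TCRBV06-05,V,CASS
TCRBV06-06,V,CASS
TCRBV06-07,V,CASS
TCRBV06-08,V,CASS
TCRBV06-09,V,CASS
TCRBV07-01,V,CASS
TCRBV07-02,V,CASS
TCRBV07-03,V,CASS
TCRBV07-04,V,CASS
TCRBV07-05,V,CASS
TCRBV07-06,V,CASS
TCRBV07-07,V,CASS
TCRBV07-08,V,CASS
TCRBV07-09,V,CASS
TCRBV07-10,V,CASS
TCRBV08-01,V,CASS
TCRBV08-02,V,CASS
TCRBV09-01,V,CASS
TCRBV10-01,V,CASS
TCRBV10-02,V,CASS
TCRBV10-03,V,CASS
TCRBV11-01,V,CASS
TCRBV11-02,V,CASS
TCRBV11-03,V,CASS
TCRBV12-01,V,CASS
TCRBV12-02,V,CASS
TCRBV12-03,V,CASS
TCRBV12-04,V,CASS
TCRBV12-05,V,CASS
TCRBV12-06,V,CASS
TCRBV13-01,V,CASS
TCRBV14-01,V,CASS
TCRBV15-01,V,CATS
TCRBV16-01,V,CASS
TCRBV17-01,V,CASS
TCRBV18-01,V,CASS
TCRBV19-01,V,CASS
TCRBV20-01,V,CSAR
TCRBV21-01,V,CASS
TCRBV22-01,V,CASS
TCRBV23-01,V,CASS
TCRBV24-01,V,CATS
TCRBV25-01,V,CASS
TCRBV26-01,V,CASS
TCRBV27-01,V,CASS
TCRBV28-01,V,CASS
TCRBV29-01,V,CSVE
TCRBV30-01,V,CAW
TCRBJ01-01,J,NTEAFF
TCRBJ01-02,J,NYGYTF
TCRBJ01-03,J,SGNTIYF
TCRBJ01-04,J,TNEKLFF
TCRBJ01-05,J,SNQPQHF
TCRBJ01-06,J,SYNSPLHF
TCRBJ02-01,J,SYNEQFF
TCRBJ02-02,J,NTGELFF
TCRBJ02-03,J,STDTQYF
TCRBJ02-04,J,AKNIQYF
TCRBJ02-05,J,QETQYF
TCRBJ02-06,J,SGANVLTF
TCRBJ02-07,J,SYEQYF
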