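marker,species,peptide,t_r_min,t_r_sd_min,dp_v,precursor_mz,precursor_charge,rank,product_label,product_mz,ce_v,cxp_v
Alfalfa 1,Alfalfa,VEGGLSIMSPPER,4.91,0.02,71,686.4,2,1,y4,498.3,27,26
Alfalfa 1,Alfalfa,VEGGLSIMSPPER,4.91,0.02,71,686.4,2,2,y5,585.3,29,26
Alfalfa 1,Alfalfa,VEGGLSIMSPPER,4.91,0.02,71,686.4,2,3,y6,716.3,31,24
Alfalfa 2,Alfalfa,FNLEAGDIMR,5.75,0.02,56,583.3,2,1,y6,662.3,29,32
Alfalfa 2,Alfalfa,FNLEAGDIMR,5.75,0.02,56,583.3,2,2,y3,419.2,39,24
Alfalfa 2,Alfalfa,FNLEAGDIMR,5.75,0.02,56,583.3,2,3,y5,591.3,27,30
Alfalfa 3,Alfalfa,ISDVNSLTLPILR,7.60,0.01,60,720.9,2,1,y4,498.3,35,36
Alfalfa 3,Alfalfa,ISDVNSLTLPILR,7.60,0.01,60,720.9,2,2,y6,712.5,35,36
Alfalfa 3,Alfalfa,ISDVNSLTLPILR,7.60,0.01,60,720.9,2,3,b3,316.2,35,36
Broad bean 1,Broad bean,EDVLSLAPK,4.77,0.02,36,486.3,2,1,y5,515.3,23,24
Broad bean 1,Broad bean,EDVLSLAPK,4.77,0.02,36,486.3,2,2,y3,315.2,21,16
Broad bean 1,Broad bean,EDVLSLAPK,4.77,0.02,36,486.3,2,3,y6,628.4,25,32
Broad bean 2,Broad bean,FNLEEGDLIR,5.90,0.01,16,603.3,2,1,y6,702.4,31,28
Broad bean 2,Broad bean,FNLEEGDLIR,5.90,0.01,16,603.3,2,2,y3,401.3,43,22
Broad bean 2,Broad bean,FNLEEGDLIR,5.90,0.01,16,603.3,2,3,y5,573.3,31,26
Broad bean 3,Broad bean,LSPGDVLVIPAGYPVAIK,8.47,0.01,16,603.7,3,1,y9^2+,458.3,21,24
Broad bean 3,Broad bean,LSPGDVLVIPAGYPVAIK,8.47,0.01,16,603.7,3,2,y5,527.4,35,36
Broad bean 3,Broad bean,LSPGDVLVIPAGYPVAIK,8.47,0.01,16,603.7,3,3,y10^2+,514.8,15,36
Chickpea 1,Chickpea,GGLSFISPSEK,4.44,0.02,11,561.3,2,1,y5,547.3,27,28
Chickpea 1,Chickpea,GGLSFISPSEK,4.44,0.02,11,561.3,2,2,y4,460.2,37,30
Chickpea 1,Chickpea,GGLSFISPSEK,4.44,0.02,11,561.3,2,3,y6,660.4,27,30
Chickpea 2,Chickpea,IVDLAIPINTPAK,6.53,0.01,26,682.9,2,1,y7,740.4,29,42
Chickpea 2,Chickpea,IVDLAIPINTPAK,6.53,0.01,26,682.9,2,2,b3,328.2,35,22
Chickpea 2,Chickpea,IVDLAIPINTPAK,6.53,0.01,26,682.9,2,3,b6,625.4,25,30
Chickpea 3,Chickpea,SSNPFTFLVPPR,7.46,0.01,91,681.8,2,1,y3,369.2,25,24
Chickpea 3,Chickpea,SSNPFTFLVPPR,7.46,0.01,91,681.8,2,2,y4,468.3,33,22
Chickpea 3,Chickpea,SSNPFTFLVPPR,7.46,0.01,91,681.8,2,3,y5,581.4,33,32
Lentil 1,Lentil,VILEDQEQEPQHR,1.87,0.03,31,540.9,3,1,y11^2+,704.8,23,40
Lentil 1,Lentil,VILEDQEQEPQHR,1.87,0.03,31,540.9,3,2,y10^2+,648.3,21,42
Lentil 1,Lentil,VILEDQEQEPQHR,1.87,0.03,31,540.9,3,3,y11^3+,470.2,23,24
Lentil 2,Lentil,FFEVTPEK,3.93,0.01,66,498.8,2,1,y6,702.4,21,34
Lentil 2,Lentil,FFEVTPEK,3.93,0.01,66,498.8,2,2,y3,373.2,35,28
Lentil 2,Lentil,FFEVTPEK,3.93,0.01,66,498.8,2,3,y5,573.3,25,32
Lentil 3,Lentil,VVDFVISLNRPGK,5.41,0.03,101,481.9,3,1,y11^2+,623.4,19,44
Lentil 3,Lentil,VVDFVISLNRPGK,5.41,0.03,101,481.9,3,2,y3,301.2,37,20
Lentil 3,Lentil,VVDFVISLNRPGK,5.41,0.03,101,481.9,3,3,y8,884.5,27,40
Lupine blue 1,Lupine blue,QQEQQLEGELEK,2.48,0.02,36,729.9,2,1,y3,389.2,37,29
Lupine blue 1,Lupine blue,QQEQQLEGELEK,2.48,0.02,36,729.9,2,2,b3,386.2,35,18
Lupine blue 1,Lupine blue,QQEQQLEGELEK,2.48,0.02,36,729.9,2,3,y5,575.3,33,28
Lupine blue 2,Lupine blue,NTLEATFNTR,3.35,0.01,31,583.8,2,1,y7,838.4,31,50
Lupine blue 2,Lupine blue,NTLEATFNTR,3.35,0.01,31,583.8,2,2,y6,709.4,31,40
Lupine blue 2,Lupine blue,NTLEATFNTR,3.35,0.01,31,583.8,2,3,b4,458.2,21,26
Lupine blue 3,Lupine blue,ISSVNSLTLPILR,7.11,0.01,45,706.9,2,1,y4,498.3,33,22
Lupine blue 3,Lupine blue,ISSVNSLTLPILR,7.11,0.01,45,706.9,2,2,y6,712.5,31,30
Lupine blue 3,Lupine blue,ISSVNSLTLPILR,7.11,0.01,45,706.9,2,3,a4,359.2,35,24
Lupine white 1,Lupine white,NPYHFSSQR,0.49,0.06,21,379.2,3,1,y8^3+,341.2,17,20
Lupine white 1,Lupine white,NPYHFSSQR,0.49,0.06,21,379.2,3,2,b6^2+,373.7,13,24
Lupine white 1,Lupine white,NPYHFSSQR,0.49,0.06,21,379.2,3,3,y3,390.2,23,20
Lupine white 2,Lupine white,DKPSQSGPFNLR,2.83,0.02,46,449.2,3,1,y5^2+,323.7,19,16
Lupine white 2,Lupine white,DKPSQSGPFNLR,2.83,0.02,46,449.2,3,2,y5,646.4,21,30
Lupine white 2,Lupine white,DKPSQSGPFNLR,2.83,0.02,46,449.2,3,3,y4,549.3,27,40
Lupine white 3,Lupine white,AVNELTFPGSAEDIER,5.90,0.01,46,583.3,3,1,y9^2+,487.2,21,22
Lupine white 3,Lupine white,AVNELTFPGSAEDIER,5.90,0.01,46,583.3,3,2,y10^2+,560.8,15,40
Lupine white 3,Lupine white,AVNELTFPGSAEDIER,5.90,0.01,46,583.3,3,3,y3,417.2,41,22
Pea 1,Pea,ELTFPGSVQEINR,5.68,0.02,41,745.4,2,1,y9,999.5,37,48
Pea 1,Pea,ELTFPGSVQEINR,5.68,0.02,41,745.4,2,2,y9^2+,500.3,37,28
Pea 1,Pea,ELTFPGSVQEINR,5.68,0.02,41,745.4,2,3,b4,491.3,29,26
Pea 2,Pea,LSSGDVFVIPAGHPVAVK,5.72,0.02,120,598.3,3,1,y9^2+,438.3,27,34
Pea 2,Pea,LSSGDVFVIPAGHPVAVK,5.72,0.02,120,598.3,3,2,y5,513.3,37,24
Pea 2,Pea,LSSGDVFVIPAGHPVAVK,5.72,0.02,120,598.3,3,3,y11^3+,363.2,43,24
Pea 3,Pea,LTPGDVFVIPAGHPVAVR,6.57,0.01,36,615.7,3,1,y16^3+,544.3,21,28
Pea 3,Pea,LTPGDVFVIPAGHPVAVR,6.57,0.01,36,615.7,3,2,y5,541.3,35,38
Pea 3,Pea,LTPGDVFVIPAGHPVAVR,6.57,0.01,36,615.7,3,3,y9^2+,452.3,33,14
Peanut 1,Peanut,GTGNLELVAVR,4.45,0.02,96,564.8,2,1,y3,345.2,29,24
Peanut 1,Peanut,GTGNLELVAVR,4.45,0.02,96,564.8,2,2,y5,557.4,33,28
Peanut 1,Peanut,GTGNLELVAVR,4.45,0.02,96,564.8,2,3,y6,686.4,31,38
Peanut 2,Peanut,FNLAGNHEQEFLR,4.45,0.02,61,525.6,3,1,b2,262.1,23,14
Peanut 2,Peanut,FNLAGNHEQEFLR,4.45,0.02,61,525.6,3,2,y11^2+,657.3,23,40
Peanut 2,Peanut,FNLAGNHEQEFLR,4.45,0.02,61,525.6,3,3,y10^2+,600.8,23,16
Peanut 3,Peanut,WLGLSAEYGNLYR,7.02,0.01,16,771.4,2,1,a2,272.2,39,14
Peanut 3,Peanut,WLGLSAEYGNLYR,7.02,0.01,16,771.4,2,2,b2,300.2,35,18
Peanut 3,Peanut,WLGLSAEYGNLYR,7.02,0.01,16,771.4,2,3,b3,357.2,39,18
Soy 1,Soy,SQSDNFEYVSFK,5.02,0.04,31,725.8,2,1,y3,381.2,35,26
Soy 1,Soy,SQSDNFEYVSFK,5.02,0.04,31,725.8,2,2,y5,643.3,35,46
Soy 1,Soy,SQSDNFEYVSFK,5.02,0.04,31,725.8,2,3,y10,1235.6,29,52
Soy 2,Soy,EAFGVNMQIVR,5.77,0.02,61,632.3,2,1,y6,760.4,29,38
Soy 2,Soy,EAFGVNMQIVR,5.77,0.02,61,632.3,2,2,y3,387.3,29,22
Soy 2,Soy,EAFGVNMQIVR,5.77,0.02,61,632.3,2,3,y9^2+,532.3,27,34
Soy 3,Soy,FYLAGNQEQEFLK,6.00,0.01,36,793.9,2,1,b2,311.1,41,18
Soy 3,Soy,FYLAGNQEQEFLK,6.00,0.01,36,793.9,2,2,b3,424.2,35,26
Soy 3,Soy,FYLAGNQEQEFLK,6.00,0.01,36,793.9,2,3,y11^2+,638.8,33,38
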