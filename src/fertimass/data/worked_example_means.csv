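cultivar,element,source,mean,sem
CJ2,N,uptake,121.52,5.56
CJ2,N,leaf,163.14,10.34
CJ2,N,stem,77.51,16.28
CJ2,N,root,145.08,5.50
CJ2,N,weighted,125.08,11.99
CJ2,P,uptake,38.86,1.89
CJ2,P,leaf,19.84,1.29
CJ2,P,stem,13.28,1.67
CJ2,P,root,35.94,1.60
CJ2,P,weighted,19.00,1.62
CJ2,K,uptake,157.62,10.40
CJ2,K,leaf,75.25,4.00
CJ2,K,stem,110.83,12.14
CJ2,K,root,115.67,11.14
CJ2,K,weighted,94.76,7.19
CJ2,Ca,uptake,66.27,2.36
CJ2,Ca,leaf,84.04,7.64
CJ2,Ca,stem,30.04,7.30
CJ2,Ca,root,35.99,2.89
CJ2,Ca,weighted,55.78,6.84
CJ2,Fe,uptake,1.58,0.12
CJ2,Fe,leaf,0.36,0.03
CJ2,Fe,stem,0.15,0.03
CJ2,Fe,root,2.98,0.24
CJ2,Fe,weighted,0.58,0.07
CJ2,Mg,uptake,39.86,2.25
CJ2,Mg,leaf,37.98,3.12
CJ2,Mg,stem,10.20,2.02
CJ2,Mg,root,22.83,1.46
CJ2,Mg,weighted,24.60,2.39
CJ2,Mn,uptake,0.19,0.01
CJ2,Mn,leaf,0.20,0.02
CJ2,Mn,stem,0.23,0.03
CJ2,Mn,root,0.37,0.03
CJ2,Mn,weighted,0.23,0.02
CJ2,B,uptake,0.07,0.00
CJ2,B,leaf,0.13,0.00
CJ2,B,stem,0.05,0.01
CJ2,B,root,0.05,0.00
CJ2,B,weighted,0.08,0.01
CJ2,Cu,uptake,0.11,0.02
CJ2,Cu,leaf,0.01,0.00
CJ2,Cu,stem,0.03,0.02
CJ2,Cu,root,0.05,0.00
CJ2,Cu,weighted,0.02,0.01
CJ2,Zn,uptake,0.10,0.02
CJ2,Zn,leaf,0.10,0.01
CJ2,Zn,stem,0.04,0.01
CJ2,Zn,root,0.10,0.00
CJ2,Zn,weighted,0.08,0.01
First Light,N,uptake,131.77,5.25
First Light,N,leaf,165.60,2.39
First Light,N,stem,82.58,6.89
First Light,N,root,139.53,1.72
First Light,N,weighted,127.70,2.46
First Light,P,uptake,38.40,3.21
First Light,P,leaf,21.70,0.44
First Light,P,stem,15.69,1.05
First Light,P,root,30.62,1.39
First Light,P,weighted,20.56,0.51
First Light,K,uptake,169.41,13.30
First Light,K,leaf,77.74,2.00
First Light,K,stem,135.90,9.54
First Light,K,root,105.29,4.08
First Light,K,weighted,105.70,3.28
First Light,Ca,uptake,69.89,2.02
First Light,Ca,leaf,66.76,1.66
First Light,Ca,stem,40.54,5.55
First Light,Ca,root,29.83,2.11
First Light,Ca,weighted,50.50,2.04
First Light,Fe,uptake,1.37,0.30
First Light,Fe,leaf,0.27,0.01
First Light,Fe,stem,0.17,0.02
First Light,Fe,root,2.85,0.32
First Light,Fe,weighted,0.61,0.04
First Light,Mg,uptake,41.03,3.05
First Light,Mg,leaf,28.23,0.57
First Light,Mg,stem,11.36,1.28
First Light,Mg,root,23.35,0.88
First Light,Mg,weighted,20.58,0.55
First Light,Mn,uptake,0.17,0.02
First Light,Mn,leaf,0.27,0.01
First Light,Mn,stem,0.17,0.02
First Light,Mn,root,0.34,0.03
First Light,Mn,weighted,0.24,0.01
First Light,B,uptake,0.08,0.00
First Light,B,leaf,0.09,0.00
First Light,B,stem,0.06,0.01
First Light,B,root,0.05,0.00
First Light,B,weighted,0.07,0.00
First Light,Cu,uptake,0.07,0.04
First Light,Cu,leaf,0.01,0.00
First Light,Cu,stem,0.01,0.00
First Light,Cu,root,0.04,0.00
First Light,Cu,weighted,0.01,0.00
First Light,Zn,uptake,0.07,0.03
First Light,Zn,leaf,0.09,0.00
First Light,Zn,stem,0.04,0.00
First Light,Zn,root,0.10,0.00
First Light,Zn,weighted,0.07,0.00
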