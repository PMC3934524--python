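year,hooks_thousands,loggerhead,leatherback
1999,830.87,466,1
2000,1196.996,1098,0
2001,705.766,347,0
2002,486.707,114,3
2003,345.209,370,1
2004,336.765,467,0
2005,112.71,45,0
2006,484.933,322,0
2007,307.654,93,0
2008,323.872,32,0
2009,394.28,71,0
2010,513.453,338,3
2011,854.183,16,0
2012,996.313,161,0
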